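"""Cholesterol flip-flop detection and double-exponential interval fitting.

A flip-flop is recorded when a cholesterol molecule's head group is in one
monolayer in the previous frame and in the other in the current frame —
*and* the lipid-type of its domain changes too.  The second condition
discards regions where lateral domain drift puts the same lipid type in
both monolayers, where a leaflet change is not a meaningful transbilayer
event.

Waiting times between successive events of each molecule are pooled into a
histogram and fitted by a sum of two decaying exponentials

    P_flip(t) = A1·exp(−t/t1) + A2·exp(−t/t2),    t1 ≤ t2,

whose fast component typically tracks the trajectory frame spacing (head
groups near the bilayer centre rattling between the monolayers) while the
slow component is the physical flip-flop time.  An optional debounce
window removes such immediate-reversal pairs at detection time instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import CholesterolResidence
from .errors import FitError, MemcurvError


@dataclass
class FlipFlopRecord:
    """Per-molecule event times and the pooled inter-event intervals (ns)."""

    events: dict[int, np.ndarray]
    intervals: np.ndarray
    frame_dt: float
    debounce: float = 0.0

    @property
    def n_events(self) -> int:
        return int(sum(len(v) for v in self.events.values()))


def _debounce_events(
    times: list[float], states: list[tuple], window: float
) -> list[float]:
    """Drop pairs of events that reverse each other within ``window``.

    ``states[i]`` is (before, after) of event i.  A pair (i, i+1) is
    dropped when event i+1 restores the state before event i within the
    window; scanning repeats until stable so chains collapse fully.
    """
    times = list(times)
    states = list(states)
    changed = True
    while changed:
        changed = False
        i = 0
        while i + 1 < len(times):
            if (times[i + 1] - times[i] <= window
                    and states[i + 1][1] == states[i][0]):
                del times[i:i + 2]
                del states[i:i + 2]
                changed = True
            else:
                i += 1
    return times


def detect_flipflops(
    residences: list[CholesterolResidence],
    debounce: float = 0.0,
) -> FlipFlopRecord:
    """Detect flip-flop events from a per-frame residence series.

    An event at frame k requires both the leaflet and the domain lipid type
    of the molecule to differ from frame k−1.  Frame times must be
    uniformly spaced.  ``debounce`` (ns) > 0 removes event pairs that
    cancel within that window.
    """
    if len(residences) < 2:
        raise MemcurvError("need at least 2 frames to detect flip-flops")
    times = np.array([r.time for r in residences], dtype=float)
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9) or dts[0] <= 0:
        raise MemcurvError("frame times must be uniformly spaced and increasing")
    frame_dt = float(dts[0])

    mols = residences[0].mol_id
    events: dict[int, np.ndarray] = {}
    all_intervals = []
    for j, mol in enumerate(mols):
        ev_times: list[float] = []
        ev_states: list[tuple] = []
        for k in range(1, len(residences)):
            prev, cur = residences[k - 1], residences[k]
            s0 = (prev.leaflet[j], prev.domain_type[j])
            s1 = (cur.leaflet[j], cur.domain_type[j])
            if s0[0] != s1[0] and s0[1] != s1[1]:
                ev_times.append(float(times[k]))
                ev_states.append((s0, s1))
        if debounce > 0:
            ev_times = _debounce_events(ev_times, ev_states, debounce)
        events[int(mol)] = np.asarray(ev_times)
        if len(ev_times) >= 2:
            all_intervals.append(np.diff(ev_times))
    intervals = (np.concatenate(all_intervals) if all_intervals
                 else np.empty(0))
    return FlipFlopRecord(
        events=events, intervals=intervals, frame_dt=frame_dt, debounce=debounce
    )


@dataclass
class IntervalHistogram:
    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def interval_histogram(
    record_or_intervals, bin_width: float
) -> IntervalHistogram:
    """Histogram of inter-event intervals pooled over molecules."""
    if isinstance(record_or_intervals, FlipFlopRecord):
        intervals = record_or_intervals.intervals
    else:
        intervals = np.asarray(record_or_intervals, dtype=float)
    if intervals.size == 0:
        raise MemcurvError("no intervals to histogram")
    if bin_width <= 0:
        raise MemcurvError("bin width must be positive")
    # one bin past the max so boundary values keep the half-open convention
    # (numpy's final edge is otherwise right-inclusive)
    n_bins = int(np.floor(intervals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(intervals, bins=edges)
    return IntervalHistogram(counts=counts, bin_edges=edges)


@dataclass
class SingleExpFit:
    A: float
    t: float
    chi2: float
    aic: float


@dataclass
class ExpFitResult:
    """Double-exponential fit of the interval histogram, t1 ≤ t2."""

    A1: float
    t1: float
    A2: float
    t2: float
    stderr: np.ndarray          # (A1, t1, A2, t2)
    chi2: float
    aic: float
    single: SingleExpFit
    prefer_single: bool         # model comparison favours one timescale
    degenerate: bool            # t2/t1 < 2: two timescales not resolved
    t1_is_frame_artifact: bool = False  # t1 within 25% of the frame spacing
    notes: list[str] = field(default_factory=list)


def _two_exp(t, A1, t1, A2, t2):
    return A1 * np.exp(-t / t1) + A2 * np.exp(-t / t2)


def _one_exp(t, A, tau):
    return A * np.exp(-t / tau)


def fit_double_exponential(
    hist: IntervalHistogram,
    frame_dt: float | None = None,
) -> ExpFitResult:
    """Weighted least-squares fit of two decaying exponentials to counts.

    Bin counts are weighted by Poisson errors (σ = √max(count, 1)).
    Characteristic-time initializations are multi-started on a log grid
    spanning [bin width, max interval]; the best converged fit wins and is
    reported with t1 ≤ t2.  A single-exponential fit and an AIC comparison
    are returned alongside so callers can detect unsupported second
    timescales; if ``frame_dt`` is given, t1 within 25% of it is flagged as
    a frame-spacing artifact.

    Raises
    ------
    FitError
        If no start converges.
    """
    occupied = int(np.sum(hist.counts > 0))
    if occupied < 6:
        raise MemcurvError(
            f"need >= 6 occupied histogram bins for a 4-parameter fit, got {occupied}"
        )
    t = hist.bin_centers
    y = hist.counts.astype(float)
    sigma = np.sqrt(np.maximum(y, 1.0))
    t_max = hist.bin_edges[-1]
    amp0 = max(y.max(), 1.0)

    taus = np.geomspace(hist.bin_width, t_max, 7)
    best = None
    for i in range(len(taus)):
        for j in range(i + 1, len(taus)):
            p0 = [amp0, taus[i], 0.1 * amp0, taus[j]]
            try:
                popt, pcov = curve_fit(
                    _two_exp, t, y, p0=p0, sigma=sigma, absolute_sigma=True,
                    bounds=([0, 1e-9, 0, 1e-9], [np.inf] * 4), maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            resid = (_two_exp(t, *popt) - y) / sigma
            chi2 = float(np.sum(resid**2))
            if best is None or chi2 < best[2]:
                best = (popt, pcov, chi2)
    if best is None:
        raise FitError("double-exponential fit did not converge from any start")
    popt, pcov, chi2 = best
    perr = np.sqrt(np.diag(pcov))
    if popt[1] > popt[3]:  # order so t1 <= t2
        popt = np.array([popt[2], popt[3], popt[0], popt[1]])
        perr = np.array([perr[2], perr[3], perr[0], perr[1]])
    A1, t1, A2, t2 = popt

    single = _fit_single(t, y, sigma, taus, amp0)
    aic2 = chi2 + 2 * 4
    prefer_single = single.aic <= aic2
    degenerate = (t2 / max(t1, 1e-300)) < 2.0
    artifact = bool(
        frame_dt is not None and frame_dt > 0 and abs(t1 - frame_dt) <= 0.25 * frame_dt
    )
    notes = []
    if degenerate:
        notes.append("t2/t1 < 2: two timescales not resolved")
    if artifact:
        notes.append(
            "t1 is within 25% of the frame spacing and is likely a "
            "detection artifact (head groups oscillating near the bilayer "
            "centre); consider only t2 as the physical flip-flop time"
        )
    return ExpFitResult(
        A1=float(A1), t1=float(t1), A2=float(A2), t2=float(t2),
        stderr=perr, chi2=chi2, aic=aic2, single=single,
        prefer_single=bool(prefer_single), degenerate=bool(degenerate),
        t1_is_frame_artifact=artifact, notes=notes,
    )


def _fit_single(t, y, sigma, taus, amp0) -> SingleExpFit:
    best = None
    for tau0 in taus:
        try:
            popt, _ = curve_fit(
                _one_exp, t, y, p0=[amp0, tau0], sigma=sigma,
                absolute_sigma=True, bounds=([0, 1e-9], [np.inf] * 2),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        chi2 = float(np.sum(((_one_exp(t, *popt) - y) / sigma) ** 2))
        if best is None or chi2 < best[1]:
            best = (popt, chi2)
    if best is None:
        return SingleExpFit(A=np.nan, t=np.nan, chi2=np.inf, aic=np.inf)
    (A, tau), chi2 = best
    return SingleExpFit(A=float(A), t=float(tau), chi2=chi2, aic=chi2 + 2 * 2)


def fit_intervals_mle(
    intervals: np.ndarray,
    n_components: int = 2,
    max_iter: int = 2000,
    tol: float = 1e-10,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """EM maximum-likelihood fit of an exponential mixture to raw intervals.

    Cross-check for the histogram fit: returns ``[(weight, mean), ...]``
    sorted by mean.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < n_components:
        raise MemcurvError("not enough intervals for MLE fit")
    rng = np.random.default_rng(seed)
    q = np.quantile(x, np.linspace(0.2, 0.95, n_components))
    means = np.maximum(q * (1 + 0.01 * rng.standard_normal(n_components)), 1e-9)
    w = np.full(n_components, 1.0 / n_components)
    ll_prev = -np.inf
    for _ in range(max_iter):
        dens = w[None, :] / means[None, :] * np.exp(-x[:, None] / means[None, :])
        tot = dens.sum(axis=1, keepdims=True)
        resp = dens / np.maximum(tot, 1e-300)
        w = resp.mean(axis=0)
        means = (resp * x[:, None]).sum(axis=0) / np.maximum(resp.sum(axis=0), 1e-300)
        ll = float(np.sum(np.log(np.maximum(tot, 1e-300))))
        if ll - ll_prev < tol:
            break
        ll_prev = ll
    order = np.argsort(means)
    return [(float(w[k]), float(means[k])) for k in order]
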