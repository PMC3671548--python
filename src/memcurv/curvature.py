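"""Spectral curvature of the membrane midline.

The closed midline is represented as two parametric series ``X(l_i)`` and
``Z(l_i)`` over the arc-length parameter ``l_i = i·s``.  Both series are
unwrapped across the periodic box, split into a linear winding trend (the
net box traversal of a closed trace) plus a periodic residual, and the
residual is expanded in a discrete Fourier basis.  Short-wavelength
components (``λ ≤ λ_c``) are discarded — they carry bead-scale noise that
would otherwise dominate the derivatives — and the derivatives needed for
the signed plane-curve curvature

    κ(l) = (Ẋ Z̈ − Ż Ẍ) / (Ẋ² + Ż²)^{3/2}

are obtained by multiplying each spectral component of wavelength λ by
``i·2π/λ`` and inverse transforming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Frame, LeafletAssignment, assign_leaflets
from .errors import MemcurvError, SpectraError
from .midline import DEFAULT_R_LOC, DEFAULT_S, Midline, trace_midline

logger = logging.getLogger(__name__)

#: Default low-pass cutoff wavelength (nm).
DEFAULT_LAMBDA_C = 15.0


def unwrap_periodic(series: np.ndarray, box_length: float) -> np.ndarray:
    """Remove periodic-box jumps from a coordinate series.

    Consecutive differences are mapped to their minimum image; the result is
    a continuous series whose total span may wind the box an integer number
    of times.

    Raises
    ------
    SpectraError
        If any consecutive jump is ambiguous (minimum-image magnitude equals
        or exceeds half the box length).
    """
    series = np.asarray(series, dtype=float)
    if box_length <= 0:
        raise SpectraError("box_length must be positive")
    d = np.diff(series)
    wrapped = d - box_length * np.round(d / box_length)
    if np.any(np.abs(wrapped) >= box_length / 2 - 1e-12):
        raise SpectraError(
            "ambiguous unwrap: consecutive points are half a box apart"
        )
    return np.concatenate([[series[0]], series[0] + np.cumsum(wrapped)])


def _winding_number(unwrapped: np.ndarray, box_length: float) -> int:
    """Integer number of box lengths a closed series traverses per period."""
    steps = np.diff(unwrapped)
    typical = np.median(np.abs(steps)) * np.sign(np.median(steps)) if len(steps) else 0.0
    total = unwrapped[-1] - unwrapped[0] + typical  # continuation to point N+1
    return int(np.round(total / box_length))


@dataclass
class MidlineSpectra:
    """Filtered Fourier representation of the midline coordinates.

    ``S_X``/``S_Z`` are numpy-convention FFTs of the periodic residuals of
    the unwrapped coordinates; the linear winding trend (slope per unit arc
    length and offset) is stored separately and re-added on reconstruction
    and differentiation.
    """

    S_X: np.ndarray
    S_Z: np.ndarray
    wavelengths: np.ndarray  # per positive spectral index, nm, decreasing
    lambda_c: float
    s: float
    n: int
    slope_x: float  # winding trend dX/dl
    slope_z: float
    offset_x: float
    offset_z: float
    time: float = 0.0

    def _omega(self) -> np.ndarray:
        return 2.0 * np.pi * np.fft.fftfreq(self.n, d=self.s)

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        """Filtered (X, Z) series including the winding trend."""
        l = np.arange(self.n) * self.s
        x = np.fft.ifft(self.S_X).real + self.offset_x + self.slope_x * l
        z = np.fft.ifft(self.S_Z).real + self.offset_z + self.slope_z * l
        return x, z

    def derivatives(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(Ẋ, Ż, Ẍ, Z̈) with respect to arc-length parameter l."""
        w = self._omega()
        xd = np.fft.ifft(1j * w * self.S_X).real + self.slope_x
        zd = np.fft.ifft(1j * w * self.S_Z).real + self.slope_z
        xdd = np.fft.ifft(-(w**2) * self.S_X).real
        zdd = np.fft.ifft(-(w**2) * self.S_Z).real
        return xd, zd, xdd, zdd


def midline_spectra(
    midline: Midline, lambda_c: float = DEFAULT_LAMBDA_C
) -> MidlineSpectra:
    """FFT of the unwrapped midline coordinates with a hard low-pass filter.

    Components with wavelength ``λ ≤ lambda_c`` are zeroed; the DC term and
    the linear winding trend are always preserved.  ``lambda_c = 0`` is the
    identity filter.
    """
    n = midline.n_points
    if n < 8:
        raise SpectraError(f"need >= 8 midline points for spectra, got {n}")
    series = {}
    for name, ax in (("x", 0), ("z", 2)):
        raw = midline.points[:, ax]
        if midline.box.periodic[ax]:
            u = unwrap_periodic(raw, midline.box.lengths[ax])
            w = _winding_number(u, midline.box.lengths[ax])
            slope = w * midline.box.lengths[ax] / (n * midline.s)
        else:
            u, slope = np.asarray(raw, dtype=float), 0.0
        l = np.arange(n) * midline.s
        resid = u - u[0] - slope * l
        series[name] = (np.fft.fft(resid), slope, float(u[0]))

    k = np.abs(np.fft.fftfreq(n, d=1.0)) * n  # integer harmonic index
    with np.errstate(divide="ignore"):
        lam = np.where(k > 0, n * midline.s / np.maximum(k, 1e-300), np.inf)
    keep = lam > lambda_c  # hard cutoff; DC (λ=inf) always kept
    S_X = np.where(keep, series["x"][0], 0.0)
    S_Z = np.where(keep, series["z"][0], 0.0)
    half = np.arange(1, n // 2 + 1)
    return MidlineSpectra(
        S_X=S_X,
        S_Z=S_Z,
        wavelengths=n * midline.s / half,
        lambda_c=lambda_c,
        s=midline.s,
        n=n,
        slope_x=series["x"][1],
        slope_z=series["z"][1],
        offset_x=series["x"][2],
        offset_z=series["z"][2],
        time=midline.time,
    )


@dataclass
class CurvatureProfile:
    """Signed curvature κ(l_i) along one frame's midline (nm⁻¹)."""

    kappa: np.ndarray
    l: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.l = np.asarray(self.l, dtype=float)
        if not np.all(np.isfinite(self.kappa)):
            raise MemcurvError("curvature profile contains non-finite values")


def curvature_profile(spectra: MidlineSpectra) -> CurvatureProfile:
    """Signed parametric curvature from filtered spectra.

    Raises
    ------
    SpectraError
        If the parameterization is degenerate (Ẋ² + Ż² < 1e-12 anywhere).
    """
    xd, zd, xdd, zdd = spectra.derivatives()
    speed2 = xd**2 + zd**2
    if np.any(speed2 < 1e-12):
        raise SpectraError("vanishing parameterization speed; midline degenerate")
    kappa = (xd * zdd - zd * xdd) / speed2**1.5
    l = np.arange(spectra.n) * spectra.s
    return CurvatureProfile(kappa=kappa, l=l, time=spectra.time)


def mean_curvature(profile: CurvatureProfile) -> float:
    """Mean absolute curvature ⟨|κ|⟩ over the midline points (nm⁻¹)."""
    if len(profile.kappa) == 0:
        raise MemcurvError("empty curvature profile")
    return float(np.mean(np.abs(profile.kappa)))


def frame_curvature(
    frame: Frame,
    leaflets: LeafletAssignment,
    s: float = DEFAULT_S,
    r_loc: float = DEFAULT_R_LOC,
    lambda_c: float = DEFAULT_LAMBDA_C,
) -> tuple[Midline, CurvatureProfile]:
    """Trace the midline of one frame and compute its curvature profile."""
    ml = trace_midline(frame, leaflets, s=s, r_loc=r_loc)
    return ml, curvature_profile(midline_spectra(ml, lambda_c=lambda_c))


def curvature_timeseries(
    frames,
    s: float = DEFAULT_S,
    r_p: float = 2.0,
    r_loc: float = DEFAULT_R_LOC,
    lambda_c: float = DEFAULT_LAMBDA_C,
    max_skip_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-frame mean |κ| over a trajectory.

    Leaflets are assigned on the first frame only and propagated by molecule
    identity.  Frames whose midline trace or spectra fail are skipped with a
    warning; more than ``max_skip_fraction`` skipped frames is an error.

    Returns a DataFrame with columns ``time``, ``mean_abs_curvature``,
    ``n_points``.
    """
    frames = list(frames)
    if not frames:
        raise MemcurvError("empty trajectory")
    leaflets = assign_leaflets(frames[0], r_p=r_p)
    rows, skipped = [], 0
    for i, fr in enumerate(frames):
        try:
            ml, prof = frame_curvature(fr, leaflets, s=s, r_loc=r_loc,
                                       lambda_c=lambda_c)
            rows.append((fr.time, mean_curvature(prof), ml.n_points))
        except MemcurvError as e:
            skipped += 1
            logger.warning("frame %d (t=%.3f ns) skipped: %s", i, fr.time, e)
    if skipped > max_skip_fraction * len(frames):
        raise MemcurvError(
            f"{skipped}/{len(frames)} frames failed curvature analysis"
        )
    return pd.DataFrame(rows, columns=["time", "mean_abs_curvature", "n_points"])
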