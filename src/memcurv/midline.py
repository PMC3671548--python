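"""Bilayer midline reconstruction for membranes curved in the XZ plane.

The membrane is assumed to be strongly curved in XZ and nearly planar along
Y (valid when the Y box dimension is small compared with X and Z).  Its
shape is then a closed plane curve which we trace point by point:

1. ``local_frame(p)`` returns the local bilayer centre and upward normal
   around an arbitrary point: the centroid of each leaflet's marker beads
   within a lateral (XZ) radius ``r_loc`` of ``p`` is computed, the centre
   is their midpoint and the normal the unit inter-centroid direction,
   projected into the XZ plane.
2. ``trace_midline`` starts at a lipid marker, steps a fixed arc distance
   ``s`` along the local tangent ``n × ĵ`` and re-centres each predicted
   point with ``local_frame``.  The trace closes when it returns to within
   ``s`` of its starting point, yielding midline points with arc-length
   parameters ``l_i = i·s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Box, Frame, LeafletAssignment, minimum_image_displacement
from .errors import LocalFrameError, MidlineError

#: Default lateral smoothing radius for the local bilayer frame (nm).
DEFAULT_R_LOC = 3.0
#: Default midline point spacing (nm).
DEFAULT_S = 1.0

_J = np.array([0.0, 1.0, 0.0])  # unit vector normal to the XZ working plane


@dataclass
class LocalFrameResult:
    center: np.ndarray  # (3,) nm
    normal: np.ndarray  # (3,) unit vector in the XZ plane, upward-pointing


@dataclass
class Midline:
    """Ordered closed sequence of bilayer-centre points.

    ``l`` holds the arc-length parameter ``l_i = i·s``; the Y component of
    the points is carried along but plays no role in the curvature.
    """

    points: np.ndarray  # (N, 3) nm
    s: float
    box: Box
    closed: bool = True
    time: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 3:
            raise MidlineError(f"midline needs >= 3 points, got {len(self.points)}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def l(self) -> np.ndarray:
        return np.arange(self.n_points) * self.s

    def step_lengths(self) -> np.ndarray:
        """PBC length of each segment, including the closing one."""
        nxt = np.roll(self.points, -1, axis=0)
        d = minimum_image_displacement(nxt - self.points, self.box)
        return np.linalg.norm(d, axis=1)

    def length(self) -> float:
        """Total traced length (sum of PBC segment lengths)."""
        return float(np.sum(self.step_lengths()))


def _pbc_mean_about(coords: np.ndarray, p: np.ndarray, box: Box) -> np.ndarray:
    """Centroid of coords expressed in the periodic image nearest to p."""
    d = minimum_image_displacement(coords - p, box)
    return p + d.mean(axis=0)


def _initial_axis(p: np.ndarray, frame: Frame,
                  leaflets: LeafletAssignment) -> np.ndarray:
    """Crude local normal: direction between the nearest marker of each leaflet."""
    near = {}
    for leaflet in ("upper", "lower"):
        idx = leaflets.marker_indices(frame, leaflet)
        d = minimum_image_displacement(frame.coords[idx] - p, frame.box)
        near[leaflet] = d[np.argmin(np.linalg.norm(d, axis=1))]
    axis = near["upper"] - near["lower"]
    axis[1] = 0.0
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise LocalFrameError("cannot estimate a local normal direction")
    return axis / norm


def local_frame(
    p: np.ndarray,
    frame: Frame,
    leaflets: LeafletAssignment,
    r_loc: float = DEFAULT_R_LOC,
    axial_cut: float = 4.0,
    axis_hint: np.ndarray | None = None,
) -> LocalFrameResult:
    """Local bilayer centre and upward unit normal around point ``p``.

    Marker beads of each leaflet inside a cylinder around ``p`` — radius
    ``r_loc`` perpendicular to the local normal (in the XZ working plane, Y
    spans the whole ribbon) and half-height ``axial_cut`` along it — are
    averaged; the centre is the midpoint of the two leaflet centroids and
    the normal the unit inter-centroid direction (lower → upper) in XZ.

    Markers are averaged with Gaussian weights in the lateral coordinate
    (σ = r_loc/3, shifted so the weight reaches zero exactly at r_loc)
    rather than uniformly: a hard window would make the centroid — and
    through it the normal — jump whenever a marker column crosses the
    window edge, imprinting the marker-grid spacing on the midline.

    The cylinder axis starts from ``axis_hint`` (the previous step's normal
    during tracing) or, failing that, the direction between the nearest
    marker of each leaflet, and is refined by one re-selection pass with
    the computed normal.

    Raises
    ------
    LocalFrameError
        If either leaflet has fewer than 3 markers inside the cylinder.
    """
    p = np.asarray(p, dtype=float).reshape(3)
    axis = (np.asarray(axis_hint, dtype=float)
            if axis_hint is not None else _initial_axis(p, frame, leaflets))
    axis = axis.copy()
    axis[1] = 0.0
    axis /= np.linalg.norm(axis)

    idx = {lf: leaflets.marker_indices(frame, lf) for lf in ("upper", "lower")}
    disp = {lf: minimum_image_displacement(frame.coords[idx[lf]] - p, frame.box)
            for lf in ("upper", "lower")}
    sig2 = (r_loc / 3.0) ** 2
    w_edge = np.exp(-(r_loc**2) / (2.0 * sig2))
    cents = {}
    for _pass in range(2):  # select -> tangent/normal -> reselect
        cov = np.zeros((2, 2))
        for leaflet in ("upper", "lower"):
            d = disp[leaflet]
            axial = d[:, 0] * axis[0] + d[:, 2] * axis[2]
            lat = np.hypot(d[:, 0] - axial * axis[0], d[:, 2] - axial * axis[2])
            near = (lat < r_loc) & (np.abs(axial) < axial_cut)
            n_near = int(near.sum())
            if n_near < 3:
                raise LocalFrameError(
                    f"only {n_near} '{leaflet}' markers within r_loc={r_loc} nm "
                    f"of {p}"
                )
            w = np.exp(-lat[near] ** 2 / (2.0 * sig2)) - w_edge
            cent = (d[near] * w[:, None]).sum(axis=0) / w.sum()
            cents[leaflet] = p + cent
            # pooled, per-leaflet-centred scatter in XZ: its principal axis
            # is the local surface tangent and, unlike the inter-centroid
            # direction, is first-order insensitive to tilt of the
            # selection axis
            dx = d[near, 0] - cent[0]
            dz = d[near, 2] - cent[2]
            cov += np.array(
                [[np.sum(w * dx * dx), np.sum(w * dx * dz)],
                 [np.sum(w * dx * dz), np.sum(w * dz * dz)]]
            )
        evals, evecs = np.linalg.eigh(cov)
        tx, tz = evecs[:, np.argmax(evals)]  # tangent in XZ
        n = np.array([-tz, 0.0, tx])
        sep = cents["upper"] - cents["lower"]
        if np.hypot(sep[0], sep[2]) < 1e-12:
            raise LocalFrameError(
                "degenerate normal: leaflet centroids coincide in XZ"
            )
        if n[0] * sep[0] + n[2] * sep[2] < 0:  # orient lower -> upper
            n = -n
        axis = n
    center = 0.5 * (cents["upper"] + cents["lower"])
    return LocalFrameResult(center=center, normal=axis)


def _tangent(normal: np.ndarray) -> np.ndarray:
    """Unit tangent n × ĵ, perpendicular to the normal in the XZ plane."""
    t = np.cross(normal, _J)
    return t / np.linalg.norm(t)


def _resample_closed(points: np.ndarray, box: Box, s: float) -> np.ndarray:
    """Resample a closed polyline to exactly uniform arc spacing.

    The raw trace ends with a seam segment of arbitrary length (< s), which
    would break the uniform-spacing assumption the spectral curvature
    relies on; linear resampling of the closed polyline at
    ``total_length / round(total_length / s)`` removes it.
    """
    steps = minimum_image_displacement(
        np.roll(points, -1, axis=0) - points, box
    )
    seg = np.linalg.norm(steps, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])  # length n+1, closed
    total = cum[-1]
    n_new = max(3, int(round(total / s)))
    if total / n_new >= s:  # keep every segment, incl. the closing one, < s
        n_new += 1
    targets = np.arange(n_new) * total / n_new
    j = np.searchsorted(cum, targets, side="right") - 1
    j = np.clip(j, 0, len(seg) - 1)
    frac = (targets - cum[j]) / np.maximum(seg[j], 1e-300)
    return points[j] + steps[j] * frac[:, None]


def trace_midline(
    frame: Frame,
    leaflets: LeafletAssignment,
    s: float = DEFAULT_S,
    r_loc: float = DEFAULT_R_LOC,
    max_steps: int | None = None,
    start_mol: int | None = None,
) -> Midline:
    """Trace the closed membrane midline at arc spacing ``s``.

    Starts at the marker bead of the lipid with the lowest molecule_id
    (or of ``start_mol`` if given; the trace is invariant to this choice
    up to a cyclic shift).
    Each step predicts the next point a distance ``s`` along the tangent
    ``n_k × ĵ`` (sign fixed to advance in +X on the first step, then kept
    by continuity) and refines it with one :func:`local_frame` call.  The
    trace terminates, marked closed, when the PBC distance from the newly
    refined point back to the first point drops below ``s`` after at least
    two steps.

    Raises
    ------
    MidlineError
        If ``max_steps`` (default ``4·Lx/s``) is exhausted without closure.
    LocalFrameError
        Propagated from a failed local frame, annotated with the step index.
    """
    if max_steps is None:
        max_steps = int(4 * frame.box.lengths[0] / s) + 8

    midx = frame.marker_indices()
    if start_mol is None:
        start_bead = midx[np.argmin(frame.molecule_id[midx])]
    else:
        hits = midx[frame.molecule_id[midx] == start_mol]
        if len(hits) == 0:
            raise MidlineError(f"start_mol {start_mol} has no marker bead")
        start_bead = hits[0]
    lf = local_frame(frame.coords[start_bead], frame, leaflets, r_loc)
    points = [lf.center]
    t = _tangent(lf.normal)
    if t[0] < 0:
        t = -t
    for k in range(1, max_steps + 1):
        approx = points[-1] + t * s
        try:
            lf = local_frame(approx, frame, leaflets, r_loc,
                             axis_hint=lf.normal)
        except LocalFrameError as e:
            raise LocalFrameError(f"step {k}: {e}") from e
        # re-centre only along the local normal: the tangential coordinate
        # of the prediction is kept, so the arc spacing stays uniform at s
        # instead of inheriting the marker-grid granularity of the local
        # centroid
        corr = minimum_image_displacement(lf.center - approx, frame.box)
        lf.center = approx + np.dot(corr, lf.normal) * lf.normal
        d = np.linalg.norm(
            minimum_image_displacement(lf.center - points[0], frame.box)
        )
        if d < s and k > 1:
            pts = _resample_closed(np.asarray(points), frame.box, s)
            # the membrane is treated as uniform along Y, so the midline's Y
            # coordinate is reported at the ribbon mid-plane (it is carried
            # but plays no role in the curvature)
            pts[:, 1] = frame.box.lengths[1] / 2.0
            return Midline(
                points=pts, s=s, box=frame.box, closed=True,
                time=frame.time,
            )
        points.append(lf.center)
        t_new = _tangent(lf.normal)
        if np.dot(t_new, t) < 0:  # keep direction through vertical segments
            t_new = -t_new
        t = t_new
    raise MidlineError(f"midline did not close within {max_steps} steps")
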