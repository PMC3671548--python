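"""Synthetic curved-membrane generator with analytic ground truth.

Real inputs to this package are coarse-grained MD trajectories of strongly
curved bilayers.  For testing, this module builds frames whose midline is a
prescribed periodic plane curve in the XZ plane, so every quantity the
analysis estimates — leaflet labels, midline position, arc length, signed
curvature, cholesterol residence, flip-flop event times — is known in
closed form.

Geometry: marker beads are placed on the two leaflet surfaces obtained by
offsetting the curve by ±h/2 along its local normal (constant bilayer
thickness even in bent regions), on a regular grid in arc length and in Y.
Lipid types are laid out in block domains along the arc, with the block
pattern inverted between the leaflets so the bilayer is asymmetric
everywhere (an upper DOPC block faces a lower DOPS block and vice versa).
Optional cholesterol head beads sit slightly inside their leaflet's marker
surface.  Isotropic Gaussian positional noise emulates thermal disorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .core import (
    CHOL_HEAD,
    DEFAULT_R_P,
    LIPID_MARKER,
    Box,
    DomainAssignment,
    Frame,
    LeafletAssignment,
)
from .errors import MemcurvError

_DENSE = 8192  # dense parameter grid for arc-length tables


class GraphCurve:
    """Periodic plane curve z = f(x) with period ``period`` (nm).

    Subclasses provide ``f``, ``fp`` (f'), ``fpp`` (f'').  Arc length is
    tabulated on a dense grid and inverted by interpolation.  Traversal is
    in +X, so the signed curvature is κ = f''/(1 + f'²)^{3/2} and the
    upward normal is (−f', 0, 1)/√(1 + f'²).
    """

    closed_in_space = False

    def __init__(self, period: float):
        if period <= 0:
            raise MemcurvError("curve period must be positive")
        self.period = float(period)
        x = np.linspace(0.0, self.period, _DENSE + 1)
        speed = np.sqrt(1.0 + self.fp(x) ** 2)
        self._x_grid = x
        self._l_grid = cumulative_trapezoid(speed, x, initial=0.0)

    # subclasses override
    def f(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def fp(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def fpp(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def total_arclength(self) -> float:
        return float(self._l_grid[-1])

    def x_at_arclength(self, l) -> np.ndarray:
        l = np.asarray(l, dtype=float) % self.total_arclength
        return np.interp(l, self._l_grid, self._x_grid)

    def point_at_arclength(self, l) -> np.ndarray:
        x = self.x_at_arclength(l)
        return np.column_stack([x, np.zeros_like(x), self.f(x)])

    def normal_at_arclength(self, l) -> np.ndarray:
        x = self.x_at_arclength(l)
        fp = self.fp(x)
        v = np.sqrt(1.0 + fp**2)
        return np.column_stack([-fp / v, np.zeros_like(x), 1.0 / v])

    def curvature_at_x(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.fpp(x) / (1.0 + self.fp(x) ** 2) ** 1.5

    def curvature_at_arclength(self, l) -> np.ndarray:
        return self.curvature_at_x(self.x_at_arclength(l))


class FlatCurve(GraphCurve):
    """z = 0: the planar-bilayer limit."""

    def f(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    fp = f
    fpp = f


class SinusoidCurve(GraphCurve):
    """z = A sin(2πx/wavelength); period may span several wavelengths."""

    def __init__(self, amplitude: float, wavelength: float, period: float | None = None):
        self.amplitude = float(amplitude)
        self.wavelength = float(wavelength)
        super().__init__(period if period is not None else wavelength)

    def f(self, x):
        return self.amplitude * np.sin(2 * np.pi * np.asarray(x, float) / self.wavelength)

    def fp(self, x):
        w = 2 * np.pi / self.wavelength
        return self.amplitude * w * np.cos(w * np.asarray(x, float))

    def fpp(self, x):
        w = 2 * np.pi / self.wavelength
        return -self.amplitude * w**2 * np.sin(w * np.asarray(x, float))


class FourierCurve(GraphCurve):
    """z = Σ_k a_k sin(2πk·x/period + φ_k) for coeffs {k: (a_k, φ_k)}."""

    def __init__(self, coeffs: dict[int, tuple[float, float]], period: float):
        self.coeffs = {int(k): (float(a), float(p)) for k, (a, p) in coeffs.items()}
        super().__init__(period)

    def f(self, x):
        x = np.asarray(x, dtype=float)
        z = np.zeros_like(x)
        for k, (a, p) in self.coeffs.items():
            z += a * np.sin(2 * np.pi * k * x / self.period + p)
        return z

    def fp(self, x):
        x = np.asarray(x, dtype=float)
        z = np.zeros_like(x)
        for k, (a, p) in self.coeffs.items():
            w = 2 * np.pi * k / self.period
            z += a * w * np.cos(w * x + p)
        return z

    def fpp(self, x):
        x = np.asarray(x, dtype=float)
        z = np.zeros_like(x)
        for k, (a, p) in self.coeffs.items():
            w = 2 * np.pi * k / self.period
            z -= a * w**2 * np.sin(w * x + p)
        return z


class CircleCurve:
    """Closed circle of radius R in the XZ plane (vesicle cross-section).

    Traversed counter-clockwise, so κ = +1/R and the normal points outward
    (the outer leaflet is 'upper').
    """

    closed_in_space = True

    def __init__(self, radius: float, center: tuple[float, float] = (0.0, 0.0)):
        if radius <= 0:
            raise MemcurvError("circle radius must be positive")
        self.radius = float(radius)
        self.center = (float(center[0]), float(center[1]))

    @property
    def total_arclength(self) -> float:
        return 2.0 * np.pi * self.radius

    def point_at_arclength(self, l) -> np.ndarray:
        th = np.asarray(l, dtype=float) / self.radius
        return np.column_stack([
            self.center[0] + self.radius * np.cos(th),
            np.zeros_like(th),
            self.center[1] + self.radius * np.sin(th),
        ])

    def normal_at_arclength(self, l) -> np.ndarray:
        th = np.asarray(l, dtype=float) / self.radius
        return np.column_stack([np.cos(th), np.zeros_like(th), np.sin(th)])

    def curvature_at_arclength(self, l) -> np.ndarray:
        return np.full(np.asarray(l, dtype=float).shape, 1.0 / self.radius)


@dataclass
class SyntheticMembraneSpec:
    """Recipe for one synthetic membrane frame.

    ``leaflet_offset`` is the distance h/2 from the midline to each leaflet
    surface (half the bilayer thickness), so the leaflets are 2·offset
    apart — which must exceed the leaflet-assignment cutoff r_p for the
    connectivity graph to separate them.
    """

    curve: GraphCurve | CircleCurve
    box_y: float = 12.4
    box_z: float | None = None  # auto: membrane extent + margin
    leaflet_offset: float = 2.0
    spacing_along: float = 0.8
    spacing_y: float = 0.9
    block_types_upper: tuple[str, ...] = ("DOPC", "DOPS")
    block_types_lower: tuple[str, ...] = ("DOPS", "DOPC")
    n_chol: int = 0
    chol_placements: list[tuple[str, float, float]] | None = None  # (leaflet, l, y)
    chol_inset: float = 0.6
    chol_boundary_margin: float = 1.5
    noise_sigma: float = 0.1
    seed: int = 0
    time: float = 0.0

    def validate(self) -> None:
        if self.spacing_along <= 0 or self.spacing_y <= 0:
            raise MemcurvError("marker spacings must be positive")
        if self.spacing_along >= DEFAULT_R_P or self.spacing_y >= DEFAULT_R_P:
            raise MemcurvError(
                f"marker spacing must stay below r_p={DEFAULT_R_P} nm for "
                "leaflet connectivity"
            )
        if 2 * self.leaflet_offset <= DEFAULT_R_P:
            raise MemcurvError(
                "leaflet separation 2·offset must exceed r_p to keep the "
                "leaflet graphs disjoint"
            )
        if len(self.block_types_upper) != len(self.block_types_lower):
            raise MemcurvError("block type lists must have equal length")
        if self.noise_sigma < 0 or self.n_chol < 0:
            raise MemcurvError("noise_sigma and n_chol must be non-negative")


@dataclass
class MembraneGroundTruth:
    """Analytic truth tables accompanying a generated frame."""

    lipids: pd.DataFrame  # molecule_id, leaflet, domain, domain_type, l, y
    chol: pd.DataFrame    # molecule_id, leaflet, domain, domain_type, l, y
    midline_l: np.ndarray
    midline_points: np.ndarray  # (M, 3), in frame coordinates
    midline_kappa: np.ndarray
    curve: GraphCurve | CircleCurve
    arclength: float
    z_shift: float

    def leaflet_assignment(self, r_p: float = DEFAULT_R_P) -> LeafletAssignment:
        mol = {int(r.molecule_id): r.leaflet for r in self.lipids.itertuples()}
        return LeafletAssignment(mol_leaflet=mol, r_p=r_p)

    def domain_assignment(self) -> DomainAssignment:
        dom = {int(r.molecule_id): r.domain for r in self.lipids.itertuples()}
        typ = {int(r.molecule_id): r.domain_type for r in self.lipids.itertuples()}
        return DomainAssignment(mol_domain=dom, mol_domain_type=typ)


def _block_of(l: np.ndarray, arclength: float, n_blocks: int) -> np.ndarray:
    b = np.floor((np.asarray(l, dtype=float) % arclength) / arclength * n_blocks)
    return np.minimum(b.astype(int), n_blocks - 1)


def _counts(spec: SyntheticMembraneSpec) -> tuple[int, int]:
    n_along = max(3, int(round(spec.curve.total_arclength / spec.spacing_along)))
    n_y = max(1, int(round(spec.box_y / spec.spacing_y)))
    return n_along, n_y


def generate_membrane(
    spec: SyntheticMembraneSpec,
    rng: np.random.Generator | None = None,
    n_along: int | None = None,
    n_y: int | None = None,
) -> tuple[Frame, MembraneGroundTruth]:
    """Build one frame plus its ground-truth tables.

    ``n_along``/``n_y`` override the marker counts derived from the spec's
    spacings (used by :func:`generate_trajectory` to keep the topology
    constant while the curve morphs).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    curve = spec.curve
    arclen = curve.total_arclength
    if n_along is None or n_y is None:
        na, ny = _counts(spec)
        n_along = n_along if n_along is not None else na
        n_y = n_y if n_y is not None else ny

    n_blocks = len(spec.block_types_upper)
    l_mark = np.arange(n_along) * arclen / n_along
    y_rows = (np.arange(n_y) + 0.5) * spec.box_y / n_y
    mid = curve.point_at_arclength(l_mark)
    nrm = curve.normal_at_arclength(l_mark)
    block = _block_of(l_mark, arclen, n_blocks)

    # box: graph curves wind the box in X; a circle needs room on all sides
    if isinstance(curve, CircleCurve):
        extent = 2 * (curve.radius + spec.leaflet_offset)
        box_x = extent + 8.0
        periodic = np.array([True, True, True])
        x_shift = box_x / 2 - curve.center[0]
    else:
        box_x = curve.period
        periodic = np.array([True, True, True])
        x_shift = 0.0
    zlo = mid[:, 2].min() - spec.leaflet_offset
    zhi = mid[:, 2].max() + spec.leaflet_offset
    box_z = spec.box_z if spec.box_z is not None else (zhi - zlo) + 8.0
    z_shift = box_z / 2 - (zhi + zlo) / 2
    box = Box(lengths=np.array([box_x, spec.box_y, box_z]), periodic=periodic)

    coords, kinds, types, mols = [], [], [], []
    lip_rows = []
    mol_id = 0
    for leaflet, sign, btypes in (
        ("upper", +1.0, spec.block_types_upper),
        ("lower", -1.0, spec.block_types_lower),
    ):
        surf = mid + sign * spec.leaflet_offset * nrm
        for yi in y_rows:
            for j in range(n_along):
                ltype = btypes[block[j] % len(btypes)]
                coords.append([surf[j, 0] + x_shift, yi, surf[j, 2] + z_shift])
                kinds.append(LIPID_MARKER)
                types.append(ltype)
                mols.append(mol_id)
                lip_rows.append(
                    (mol_id, leaflet, f"{leaflet[0].upper()}:B{block[j]}", ltype,
                     float(l_mark[j]), float(yi))
                )
                mol_id += 1

    # cholesterol head beads, inset from their leaflet's marker surface
    placements = spec.chol_placements
    if placements is None and spec.n_chol > 0:
        placements = _random_chol_placements(spec, arclen, rng, n_blocks)
    placements = placements or []
    chol_rows = []
    for leaflet, l_c, y_c in placements:
        sign = +1.0 if leaflet == "upper" else -1.0
        p = curve.point_at_arclength([l_c])[0]
        n_c = curve.normal_at_arclength([l_c])[0]
        pos = p + sign * (spec.leaflet_offset - spec.chol_inset) * n_c
        b = int(_block_of(np.array([l_c]), arclen, n_blocks)[0])
        btypes = spec.block_types_upper if leaflet == "upper" else spec.block_types_lower
        coords.append([pos[0] + x_shift, y_c, pos[2] + z_shift])
        kinds.append(CHOL_HEAD)
        types.append("CHOL")
        mols.append(mol_id)
        chol_rows.append(
            (mol_id, leaflet, f"{leaflet[0].upper()}:B{b}", btypes[b % len(btypes)],
             float(l_c), float(y_c))
        )
        mol_id += 1

    coords = np.asarray(coords, dtype=float)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    coords = box.wrap(coords)

    frame = Frame(
        coords=coords,
        bead_kind=np.array(kinds, dtype=object),
        lipid_type=np.array(types, dtype=object),
        molecule_id=np.array(mols),
        box=box,
        time=spec.time,
    )

    m_dense = 512
    l_dense = np.arange(m_dense) * arclen / m_dense
    pts = curve.point_at_arclength(l_dense)
    pts = pts + np.array([x_shift, 0.0, z_shift])
    kap = curve.curvature_at_arclength(l_dense)
    # self-check: exported truth is the closed-form curvature of the curve
    assert np.allclose(kap, curve.curvature_at_arclength(l_dense))

    cols = ["molecule_id", "leaflet", "domain", "domain_type", "l", "y"]
    gt = MembraneGroundTruth(
        lipids=pd.DataFrame(lip_rows, columns=cols),
        chol=pd.DataFrame(chol_rows, columns=cols),
        midline_l=l_dense,
        midline_points=pts,
        midline_kappa=kap,
        curve=curve,
        arclength=arclen,
        z_shift=z_shift,
    )
    return frame, gt


def _random_chol_placements(
    spec: SyntheticMembraneSpec,
    arclen: float,
    rng: np.random.Generator,
    n_blocks: int,
) -> list[tuple[str, float, float]]:
    """Uniform placements kept clear of block boundaries.

    The margin avoids ambiguity between the planted domain label and the
    nearest-marker rule the analysis uses: right at a boundary either
    answer is defensible, so the generator does not plant samples there.
    """
    edges = np.arange(n_blocks + 1) * arclen / n_blocks
    placements = []
    while len(placements) < spec.n_chol:
        l_c = rng.uniform(0.0, arclen)
        if np.min(np.abs(l_c - edges)) < spec.chol_boundary_margin:
            continue
        leaflet = "upper" if rng.random() < 0.5 else "lower"
        y_c = rng.uniform(0.0, spec.box_y)
        placements.append((leaflet, float(l_c), float(y_c)))
    return placements


@dataclass
class PlantedFlip:
    """One scheduled cholesterol leaflet transition in a trajectory."""

    frame_index: int
    mol_id: int


def generate_trajectory(
    specs: list[SyntheticMembraneSpec],
    frame_dt: float = 4.0,
    flip_schedule: list[PlantedFlip] | None = None,
) -> tuple[list[tuple[Frame, MembraneGroundTruth]], pd.DataFrame]:
    """Generate a trajectory of frames with persistent molecule identity.

    The first spec fixes the topology (marker grid and cholesterol
    placements); later specs may morph the curve but keep the counts.
    ``flip_schedule`` moves the listed cholesterol molecules to the other
    leaflet at the given frame; the returned event table records each
    planted transition with its analytic residence before/after and whether
    the different-lipid-domains detection rule should count it.
    """
    if not specs:
        raise MemcurvError("empty spec schedule")
    rng = np.random.default_rng(specs[0].seed)
    n_along, n_y = _counts(specs[0])
    base = specs[0]
    arclen0 = base.curve.total_arclength
    n_blocks = len(base.block_types_upper)
    placements = base.chol_placements
    if placements is None and base.n_chol > 0:
        placements = _random_chol_placements(base, arclen0, rng, n_blocks)
    placements = list(placements or [])
    n_lipids = 2 * n_along * n_y
    for sp in specs[1:]:
        if len(sp.block_types_upper) != n_blocks:
            raise MemcurvError("block layout must be identical across the schedule")

    schedule: dict[int, list[int]] = {}
    for ev in flip_schedule or []:
        schedule.setdefault(ev.frame_index, []).append(ev.mol_id)

    frames: list[tuple[Frame, MembraneGroundTruth]] = []
    events = []
    for i, sp in enumerate(specs):
        for mol in schedule.get(i, []):
            ci = mol - n_lipids
            if not 0 <= ci < len(placements):
                raise MemcurvError(f"flip schedule names unknown cholesterol {mol}")
            leaflet, l_c, y_c = placements[ci]
            new_leaflet = "lower" if leaflet == "upper" else "upper"
            arclen_i = sp.curve.total_arclength
            b = int(_block_of(np.array([l_c % arclen_i]), arclen_i, n_blocks)[0])
            t_from = (sp.block_types_upper if leaflet == "upper"
                      else sp.block_types_lower)[b % n_blocks]
            t_to = (sp.block_types_upper if new_leaflet == "upper"
                    else sp.block_types_lower)[b % n_blocks]
            events.append((mol, i, i * frame_dt, leaflet, new_leaflet,
                           t_from, t_to, t_from != t_to))
            placements[ci] = (new_leaflet, l_c, y_c)
        sp_i = replace(sp, chol_placements=list(placements), time=i * frame_dt)
        frame, gt = generate_membrane(sp_i, rng=rng, n_along=n_along, n_y=n_y)
        frames.append((frame, gt))

    event_table = pd.DataFrame(
        events,
        columns=["mol_id", "frame", "time", "leaflet_from", "leaflet_to",
                 "domain_type_from", "domain_type_to", "counted"],
    )
    return frames, event_table


def generate_intervals(
    mixture: list[tuple[float, float]],
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` waiting times from an exponential mixture.

    ``mixture`` is a list of ``(weight, mean)`` pairs with non-negative
    weights summing to 1 and positive means.
    """
    weights = np.array([w for w, _ in mixture], dtype=float)
    means = np.array([m for _, m in mixture], dtype=float)
    if len(mixture) == 0 or np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise MemcurvError("mixture weights must be non-negative and sum to 1")
    if np.any(means <= 0):
        raise MemcurvError("mixture means must be positive")
    if n < 0:
        raise MemcurvError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = rng.choice(len(mixture), size=n, p=weights)
    return rng.exponential(means[comp])


def sinusoid_spec(
    amplitude: float,
    wavelength: float,
    seed: int = 0,
    **kwargs,
) -> SyntheticMembraneSpec:
    """Single-period sinusoid membrane z = A sin(2πx/L) in an L-long box."""
    return SyntheticMembraneSpec(
        curve=SinusoidCurve(amplitude, wavelength), seed=seed, **kwargs
    )


def preset(name: str, seed: int = 0) -> SyntheticMembraneSpec:
    """Named membrane recipes.

    - ``flat``: planar bilayer in a 100 nm box.
    - ``sinusoid``: one 50 nm period of a 5 nm-amplitude sinusoid.
    - ``paper``: meander-like sinusoid carrying the reference composition of
      4032 lipids (2016 of each type, two blocks per leaflet, inverted
      between leaflets) and 784 cholesterol in a 12.4 nm-wide ribbon.
    """
    if name == "flat":
        return SyntheticMembraneSpec(curve=FlatCurve(100.0), seed=seed)
    if name == "sinusoid":
        return sinusoid_spec(5.0, 50.0, seed=seed)
    if name == "paper":
        curve = SinusoidCurve(6.0, 74.0)
        n_along, n_y = 144, 14  # 2·144·14 = 4032 lipids
        return SyntheticMembraneSpec(
            curve=curve,
            box_y=12.4,
            spacing_along=curve.total_arclength / n_along,
            spacing_y=12.4 / n_y,
            n_chol=784,
            seed=seed,
        )
    raise MemcurvError(f"unknown preset {name!r}")


PRESETS = ("flat", "sinusoid", "paper")
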