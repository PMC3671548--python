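"""Curvature statistics and Boltzmann-inversion free-energy profiles.

Curvature magnitudes |κ| sampled either at every midline point or at the
positions of cholesterol molecules are binned into normalized
distributions.  Comparing two equilibrium distributions by

    E(κ) = −k_B T ln(P_a(κ) / P_b(κ))

gives the free energy of moving probability from condition *b* to
condition *a* as a function of curvature: with/without cholesterol, or
cholesterol-in-DOPS vs cholesterol-in-DOPC domains.  Bins with too few
samples in either distribution are masked rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import k as BOLTZMANN_J_PER_K

from .core import Box, CholesterolResidence, minimum_image_displacement
from .curvature import CurvatureProfile
from .errors import MemcurvError
from .midline import Midline

#: Simulation temperature of the reference systems (K).
DEFAULT_T = 320.0
#: Default |κ| bin width (nm⁻¹).
DEFAULT_BIN_WIDTH = 0.0085
#: Minimum samples per bin for an unmasked free-energy value.
DEFAULT_N_MIN = 10


def sample_curvature_at_points(
    profile: CurvatureProfile,
    midline: Midline,
    points: np.ndarray,
    box: Box | None = None,
) -> np.ndarray:
    """κ of the nearest midline point (PBC distance) for each query point.

    Ties go to the lower midline index.
    """
    box = box if box is not None else midline.box
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(midline.points) != len(profile.kappa):
        raise MemcurvError("profile and midline lengths differ")
    out = np.empty(len(points))
    for i, p in enumerate(points):
        d = np.linalg.norm(
            minimum_image_displacement(midline.points - p, box), axis=1
        )
        out[i] = profile.kappa[int(np.argmin(d))]
    return out


@dataclass
class CurvatureDistribution:
    """Density-normalized histogram of |κ|."""

    bin_edges: np.ndarray
    P: np.ndarray
    counts: np.ndarray
    n_samples: int
    condition: str = "all_midline"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def curvature_distribution(
    samples: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    condition: str = "all_midline",
    kappa_max: float | None = None,
) -> CurvatureDistribution:
    """Histogram of curvature magnitudes, normalized to ∫P d|κ| = 1.

    ``kappa_max`` fixes the upper edge so two distributions that will be
    compared bin-to-bin share identical binning.
    """
    samples = np.abs(np.asarray(samples, dtype=float).ravel())
    if samples.size == 0:
        raise MemcurvError("no curvature samples")
    if bin_width <= 0:
        raise MemcurvError("bin width must be positive")
    top = kappa_max if kappa_max is not None else samples.max()
    n_bins = max(1, int(np.ceil(top / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(samples, bins=edges)
    P = counts / (samples.size * bin_width)
    return CurvatureDistribution(
        bin_edges=edges, P=P, counts=counts, n_samples=samples.size,
        condition=condition,
    )


@dataclass
class FreeEnergyProfile:
    """E(κ) = −k_B T ln(P_a/P_b), masked where data are insufficient."""

    bin_centers: np.ndarray
    E_kT: np.ndarray       # units of k_B T; NaN on masked bins
    E_J: np.ndarray        # Joules; NaN on masked bins
    mask: np.ndarray       # True where the bin is masked (unreliable)
    T: float


def free_energy_profile(
    P_a: CurvatureDistribution,
    P_b: CurvatureDistribution,
    T: float = DEFAULT_T,
    n_min: int = DEFAULT_N_MIN,
) -> FreeEnergyProfile:
    """Boltzmann inversion of two curvature distributions.

    Bins where either input has fewer than ``n_min`` samples are masked
    (NaN) — no values are invented where the simulations carry no data.
    """
    if T <= 0:
        raise MemcurvError("temperature must be positive")
    if len(P_a.bin_edges) != len(P_b.bin_edges) or not np.allclose(
        P_a.bin_edges, P_b.bin_edges
    ):
        raise MemcurvError("distributions must share identical binning")
    mask = (P_a.counts < n_min) | (P_b.counts < n_min)
    E_kT = np.full(len(P_a.P), np.nan)
    ok = ~mask
    E_kT[ok] = -np.log(P_a.P[ok] / P_b.P[ok])
    return FreeEnergyProfile(
        bin_centers=P_a.bin_centers,
        E_kT=E_kT,
        E_J=BOLTZMANN_J_PER_K * T * E_kT,
        mask=mask,
        T=T,
    )


def partition_ratio(
    residences: list[CholesterolResidence],
    numerator_type: str = "DOPC",
    denominator_type: str = "DOPS",
) -> float:
    """Time-averaged cholesterol occupancy ratio between domain types.

    Counts are pooled over frames before taking the ratio (robust to
    frames where one domain type is momentarily empty).
    """
    if not residences:
        raise MemcurvError("no residence frames")
    num = sum(int(np.sum(r.domain_type == numerator_type)) for r in residences)
    den = sum(int(np.sum(r.domain_type == denominator_type)) for r in residences)
    if den == 0:
        raise MemcurvError(
            f"no cholesterol ever resides in {denominator_type} domains; "
            "ratio undefined"
        )
    return num / den
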