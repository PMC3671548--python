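"""Domain model and periodic-boundary geometry for bilayer analysis.

A :class:`Frame` is one time point of a coarse-grained membrane system,
reduced to the beads the analysis needs: one headgroup *marker* bead per
lipid (the phosphate bead in MARTINI-like models) and one head bead per
cholesterol.  All geometry is done in nanometres inside an orthorhombic,
optionally periodic box.

Leaflets are identified purely by connectivity: marker beads closer than a
cutoff ``r_p`` (default 2.0 nm) are joined into a graph whose two connected
components are the two monolayers.  This makes no assumption about a global
membrane normal and therefore works for arbitrarily curved bilayers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import LeafletError, MemcurvError

LIPID_MARKER = "lipid_marker"
CHOL_HEAD = "chol_head"

#: Default nearest-neighbour graph cutoff for leaflet assignment (nm).
DEFAULT_R_P = 2.0


@dataclass
class Box:
    """Orthorhombic box with per-axis periodicity flags. Lengths in nm."""

    lengths: np.ndarray
    periodic: np.ndarray = field(
        default_factory=lambda: np.array([True, True, True])
    )

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        self.periodic = np.asarray(self.periodic, dtype=bool).reshape(3)
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths <= 0):
            raise MemcurvError(f"box lengths must be positive and finite: {self.lengths}")

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) on periodic axes."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float)).copy()
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                coords[:, ax] -= np.floor(coords[:, ax] / L) * L
        return coords


def minimum_image_displacement(d: np.ndarray, box: Box) -> np.ndarray:
    """Map displacement vectors to their minimum periodic image."""
    d = np.asarray(d, dtype=float).copy()
    for ax in range(3):
        if box.periodic[ax]:
            L = box.lengths[ax]
            d[..., ax] -= L * np.round(d[..., ax] / L)
    return d


def minimum_image_distance(p: np.ndarray, q: np.ndarray, box: Box) -> float:
    """Distance between the closest periodic images of two points (nm)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise MemcurvError("non-finite coordinates in minimum_image_distance")
    return float(np.linalg.norm(minimum_image_displacement(q - p, box)))


def _circular_mean(x: np.ndarray, L: float) -> float:
    """Mean of points on a circle of circumference L (PBC-safe centroid)."""
    theta = 2.0 * np.pi * x / L
    ang = np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
    return float((ang % (2.0 * np.pi)) * L / (2.0 * np.pi))


def pbc_centroid(coords: np.ndarray, box: Box) -> np.ndarray:
    """Centroid of a point cloud, robust to wrapping across periodic faces."""
    coords = np.atleast_2d(coords)
    c = np.empty(3)
    for ax in range(3):
        if box.periodic[ax]:
            c[ax] = _circular_mean(coords[:, ax], box.lengths[ax])
        else:
            c[ax] = float(np.mean(coords[:, ax]))
    return c


@dataclass
class Frame:
    """One trajectory frame of marker/cholesterol beads.

    Parameters
    ----------
    coords : (n, 3) float array, nm
    bead_kind : (n,) str array, one of ``lipid_marker``/``chol_head``/``other``
    lipid_type : (n,) str array; lipid species per bead (e.g. DOPC, DOPS);
        empty string allowed for non-marker beads
    molecule_id : (n,) int array grouping beads into molecules
    box : Box
    time : float, ns
    """

    coords: np.ndarray
    bead_kind: np.ndarray
    lipid_type: np.ndarray
    molecule_id: np.ndarray
    box: Box
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.bead_kind = np.asarray(self.bead_kind, dtype=object)
        self.lipid_type = np.asarray(self.lipid_type, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        n = len(self.coords)
        if not (len(self.bead_kind) == len(self.lipid_type) == len(self.molecule_id) == n):
            raise MemcurvError("Frame arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.coords)):
            raise MemcurvError("Frame coordinates must be finite")
        mk = self.bead_kind == LIPID_MARKER
        if np.any(mk & (self.lipid_type == "")):
            raise MemcurvError("every lipid_marker bead needs a lipid_type")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bead_kind == LIPID_MARKER)

    def chol_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bead_kind == CHOL_HEAD)


@dataclass
class LeafletAssignment:
    """Partition of lipid molecules into two leaflets.

    Stored per molecule so that a first-frame assignment can be reused on
    later frames of the same topology (lipids do not flip between leaflets
    on simulation timescales).
    """

    mol_leaflet: dict[int, str]
    r_p: float = DEFAULT_R_P

    def leaflet_of_markers(self, frame: Frame) -> np.ndarray:
        idx = frame.marker_indices()
        return np.array([self.mol_leaflet[int(m)] for m in frame.molecule_id[idx]],
                        dtype=object)

    def marker_indices(self, frame: Frame, leaflet: str) -> np.ndarray:
        idx = frame.marker_indices()
        lab = self.leaflet_of_markers(frame)
        return idx[lab == leaflet]


@dataclass
class DomainAssignment:
    """Per-lipid-molecule lateral domain label and its lipid type."""

    mol_domain: dict[int, str]
    mol_domain_type: dict[int, str]

    @classmethod
    def from_lipid_types(cls, frame: Frame) -> "DomainAssignment":
        """Fallback when no block layout is known: domain = lipid type."""
        idx = frame.marker_indices()
        dom: dict[int, str] = {}
        for i in idx:
            dom[int(frame.molecule_id[i])] = str(frame.lipid_type[i])
        return cls(mol_domain=dict(dom), mol_domain_type=dom)


@dataclass
class CholesterolResidence:
    """Leaflet and lipid domain each cholesterol resides in, one frame."""

    mol_id: np.ndarray
    leaflet: np.ndarray
    domain: np.ndarray
    domain_type: np.ndarray
    time: float = 0.0


def _marker_pairs_within(coords: np.ndarray, box: Box, r_p: float) -> np.ndarray:
    """Index pairs of markers at strict PBC distance < r_p."""
    wrapped = box.wrap(coords)
    if box.periodic.all():
        tree = cKDTree(wrapped, boxsize=box.lengths)
        pairs = tree.query_pairs(r_p, output_type="ndarray")
    else:
        tree = cKDTree(wrapped)
        pairs = tree.query_pairs(r_p, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = np.linalg.norm(
        minimum_image_displacement(wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]], box),
        axis=1,
    )
    return pairs[d < r_p]  # strict cutoff: boundary is excluded


def assign_leaflets(frame: Frame, r_p: float = DEFAULT_R_P) -> LeafletAssignment:
    """Partition lipids into two leaflets by marker-bead connectivity.

    Builds the nearest-neighbour graph connecting marker beads whose PBC
    distance is strictly below ``r_p`` and requires its connected components
    to be exactly two (the two monolayers).  The component whose PBC-safe
    mean Z is larger is labelled ``upper``; for vesicle-like cross-sections
    where mean Z ties, the radially outer component is ``upper``.

    Raises
    ------
    LeafletError
        If the graph has one component (cutoff too large or leaflets in
        contact) or more than two (cutoff too small / fragmented leaflet).
    """
    idx = frame.marker_indices()
    if len(idx) < 2:
        raise MemcurvError("need at least 2 marker beads to assign leaflets")
    coords = frame.coords[idx]
    pairs = _marker_pairs_within(coords, frame.box, r_p)
    n = len(idx)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp != 2:
        raise LeafletError(n_comp)

    centroid = pbc_centroid(coords, frame.box)
    disp = minimum_image_displacement(coords - centroid, frame.box)
    mean_z = [float(np.mean(disp[labels == c, 2])) for c in (0, 1)]
    if abs(mean_z[0] - mean_z[1]) > 0.25:
        upper_comp = int(np.argmax(mean_z))
    else:
        # vesicle cross-section: both leaflets are concentric, so break the
        # tie by radial extent in the XZ working plane
        r = np.hypot(disp[:, 0], disp[:, 2])
        mean_r = [float(np.mean(r[labels == c])) for c in (0, 1)]
        upper_comp = int(np.argmax(mean_r))

    mol_leaflet: dict[int, str] = {}
    for i, comp in zip(idx, labels):
        mol_leaflet[int(frame.molecule_id[i])] = (
            "upper" if comp == upper_comp else "lower"
        )
    return LeafletAssignment(mol_leaflet=mol_leaflet, r_p=r_p)


def assign_cholesterol_residence(
    frame: Frame,
    leaflets: LeafletAssignment,
    domains: DomainAssignment,
) -> CholesterolResidence:
    """Assign each cholesterol head to the leaflet/domain of its nearest lipid.

    Nearest is by PBC distance to lipid marker beads; exact ties go to the
    marker with the lowest molecule_id so the result is deterministic.
    """
    chol = frame.chol_indices()
    markers = frame.marker_indices()
    if len(markers) == 0:
        raise MemcurvError("no lipid marker beads; cannot assign cholesterol residence")
    mcoords = frame.coords[markers]
    mmol = frame.molecule_id[markers]

    leaf = np.empty(len(chol), dtype=object)
    dom = np.empty(len(chol), dtype=object)
    dtyp = np.empty(len(chol), dtype=object)
    for j, ci in enumerate(chol):
        d = np.linalg.norm(
            minimum_image_displacement(mcoords - frame.coords[ci], frame.box), axis=1
        )
        dmin = d.min()
        ties = np.flatnonzero(d <= dmin + 1e-9)
        k = ties[np.argmin(mmol[ties])]
        mol = int(mmol[k])
        leaf[j] = leaflets.mol_leaflet[mol]
        dom[j] = domains.mol_domain[mol]
        dtyp[j] = domains.mol_domain_type[mol]
    return CholesterolResidence(
        mol_id=frame.molecule_id[chol].copy(),
        leaflet=leaf,
        domain=dom,
        domain_type=dtyp,
        time=frame.time,
    )
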