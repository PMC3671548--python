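"""Readers and writers.

Two input routes exist:

* MD formats (GRO/PDB structure plus optional XTC/TRR/DCD trajectory) via
  MDAnalysis, with marker and cholesterol beads picked by atom name
  (defaults ``PO4`` and ``ROH``).  Coordinates are converted to nm.
* A light CSV/NPZ side-channel carrying exactly the arrays a
  :class:`~memcurv.core.Frame` holds, so the algorithmic core round-trips
  without any MD toolchain.

CSV schema: comment header lines ``# box Lx Ly Lz``, ``# periodic px py
pz``, ``# time t``, then columns ``molecule_id,bead_kind,lipid_type,x,y,z``
(nm).  NPZ stores the same arrays under the same names plus ``box``,
``periodic`` and ``time``.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHOL_HEAD, LIPID_MARKER, Box, Frame
from .errors import MemcurvError
from .midline import Midline

DEFAULT_MARKER_NAME = "PO4"
DEFAULT_CHOL_NAME = "ROH"
_CHOL_RESNAMES = {"CHOL", "CHL1", "CLOL"}


def write_frame_csv(frame: Frame, path, params: dict | None = None) -> None:
    """Write a frame to the documented CSV schema (floats at full precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# memcurv frame v1\n")
        fh.write("# box %.17g %.17g %.17g\n" % tuple(frame.box.lengths))
        fh.write("# periodic %d %d %d\n" % tuple(int(p) for p in frame.box.periodic))
        fh.write("# time %.17g\n" % frame.time)
        if params:
            fh.write("# params %s\n" % json.dumps(params, sort_keys=True))
        df = pd.DataFrame(
            {
                "molecule_id": frame.molecule_id,
                "bead_kind": frame.bead_kind,
                "lipid_type": frame.lipid_type,
                "x": frame.coords[:, 0],
                "y": frame.coords[:, 1],
                "z": frame.coords[:, 2],
            }
        )
        df.to_csv(fh, index=False, float_format="%.17g")


def read_frame_csv(path) -> Frame:
    """Read a frame written by :func:`write_frame_csv`."""
    path = Path(path)
    box_lengths = periodic = None
    time = 0.0
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "box":
                    box_lengths = [float(v) for v in parts[1:4]]
                elif parts and parts[0] == "periodic":
                    periodic = [bool(int(v)) for v in parts[1:4]]
                elif parts and parts[0] == "time":
                    time = float(parts[1])
            else:
                body.append(line)
    if box_lengths is None:
        raise MemcurvError(f"{path}: missing '# box' header line")
    df = pd.read_csv(_stdio.StringIO("".join(body)), float_precision="round_trip")
    return Frame(
        coords=df[["x", "y", "z"]].to_numpy(float),
        bead_kind=df["bead_kind"].astype(str).to_numpy(object),
        lipid_type=df["lipid_type"].fillna("").astype(str).to_numpy(object),
        molecule_id=df["molecule_id"].to_numpy(np.int64),
        box=Box(lengths=np.array(box_lengths),
                periodic=np.array(periodic if periodic else [True] * 3)),
        time=time,
    )


def write_frame_npz(frame: Frame, path) -> None:
    np.savez(
        path,
        coords=frame.coords,
        bead_kind=np.asarray(frame.bead_kind, dtype=str),
        lipid_type=np.asarray(frame.lipid_type, dtype=str),
        molecule_id=frame.molecule_id,
        box=frame.box.lengths,
        periodic=frame.box.periodic,
        time=np.array(frame.time),
    )


def read_frame_npz(path) -> Frame:
    with np.load(path, allow_pickle=False) as z:
        return Frame(
            coords=z["coords"],
            bead_kind=z["bead_kind"].astype(object),
            lipid_type=z["lipid_type"].astype(object),
            molecule_id=z["molecule_id"],
            box=Box(lengths=z["box"], periodic=z["periodic"]),
            time=float(z["time"]),
        )


def _frame_from_universe(u, marker_name: str, chol_name: str, time_ns: float) -> Frame:
    import MDAnalysis  # noqa: F401  (deferred: heavy import)

    markers = u.select_atoms(f"name {marker_name} and not resname "
                             + " ".join(sorted(_CHOL_RESNAMES)))
    chol = u.select_atoms(f"name {chol_name}")
    if len(markers) == 0:
        names = sorted(set(u.atoms.names))
        raise MemcurvError(
            f"no beads named {marker_name!r}; available names: {names[:40]}"
        )
    if u.dimensions is None or np.any(u.dimensions[:3] <= 0):
        raise MemcurvError("structure/trajectory has no box information")
    sel = markers + chol
    coords = sel.positions / 10.0  # Å -> nm
    kinds = np.array(
        [LIPID_MARKER] * len(markers) + [CHOL_HEAD] * len(chol), dtype=object
    )
    types = np.array(
        [str(r) for r in markers.resnames] + ["CHOL"] * len(chol), dtype=object
    )
    mols = np.concatenate([markers.resindices, chol.resindices]).astype(np.int64)
    box = Box(lengths=u.dimensions[:3] / 10.0)
    return Frame(coords=coords, bead_kind=kinds, lipid_type=types,
                 molecule_id=mols, box=box, time=time_ns)


def read_structure_and_trajectory(
    structure,
    trajectory=None,
    marker_name: str = DEFAULT_MARKER_NAME,
    chol_name: str = DEFAULT_CHOL_NAME,
):
    """Yield :class:`Frame` objects from MD files (GRO/PDB [+ XTC/TRR/DCD]).

    MDAnalysis handles the formats; positions and box come back in nm and
    trajectory times in ns.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(structure)) if trajectory is None else mda.Universe(
        str(structure), str(trajectory)
    )
    for ts in u.trajectory:
        yield _frame_from_universe(u, marker_name, chol_name, float(ts.time) / 1000.0)


def write_frame_gro(frame: Frame, path) -> None:
    """Write a frame as a GRO file (markers as PO4, cholesterol as ROH)."""
    import MDAnalysis as mda

    n = frame.n_beads
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n),
        residue_segindex=np.zeros(n, dtype=int), trajectory=True,
    )
    names = np.where(frame.bead_kind == CHOL_HEAD, DEFAULT_CHOL_NAME,
                     DEFAULT_MARKER_NAME)
    resnames = np.where(frame.bead_kind == CHOL_HEAD, "CHOL",
                        frame.lipid_type.astype(str))
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", frame.molecule_id + 1)
    u.atoms.positions = frame.coords * 10.0  # nm -> Å
    u.dimensions = np.array(
        [*(frame.box.lengths * 10.0), 90.0, 90.0, 90.0], dtype=float
    )
    u.atoms.write(str(path))


def write_midline_csv(midline: Midline, kappa=None, path=None,
                      params: dict | None = None) -> None:
    """Midline (and optional per-point κ) as CSV: i, l, x, y, z[, kappa]."""
    with open(path, "w") as fh:
        fh.write("# memcurv midline v1\n")
        fh.write("# box %.17g %.17g %.17g\n" % tuple(midline.box.lengths))
        fh.write("# s %.17g\n" % midline.s)
        if params:
            fh.write("# params %s\n" % json.dumps(params, sort_keys=True))
        data = {
            "i": np.arange(midline.n_points),
            "l": midline.l,
            "x": midline.points[:, 0],
            "y": midline.points[:, 1],
            "z": midline.points[:, 2],
        }
        if kappa is not None:
            data["kappa"] = np.asarray(kappa)
        pd.DataFrame(data).to_csv(fh, index=False, float_format="%.17g")


def write_midline_pdb(midline: Midline, kappa, path) -> None:
    """Pseudo-atom PDB of the midline with B-factor = |κ| for visualization."""
    kappa = np.asarray(kappa, dtype=float)
    with open(path, "w") as fh:
        fh.write("REMARK membrane midline pseudo-atoms; B-factor = |kappa| (nm^-1)\n")
        for i, (p, k) in enumerate(zip(midline.points, kappa), start=1):
            x, y, z = p * 10.0  # nm -> Å
            fh.write(
                "ATOM  %5d  C   MID A%4d    %8.3f%8.3f%8.3f%6.2f%6.2f\n"
                % (i % 100000, i % 10000, x, y, z, 1.0, abs(k))
            )
        fh.write("END\n")
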