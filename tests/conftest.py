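import numpy as np
import pytest

import memcurv as mc


@pytest.fixture(scope="session")
def sinusoid_membrane():
    """Default sinusoid membrane (A=5 nm, L=50 nm, sigma=0.1 nm) + truth."""
    spec = mc.sinusoid_spec(5.0, 50.0, seed=101)
    frame, gt = mc.generate_membrane(spec)
    return frame, gt


@pytest.fixture(scope="session")
def flat_membrane():
    spec = mc.preset("flat", seed=102)
    frame, gt = mc.generate_membrane(spec)
    return frame, gt


@pytest.fixture(scope="session")
def paper_membrane():
    spec = mc.preset("paper", seed=103)
    frame, gt = mc.generate_membrane(spec)
    return frame, gt


def two_flat_sheets(n_side=10, gap=4.0, spacing=1.0):
    """Minimal hand-built bilayer: two square marker grids at z = ±gap/2."""
    xs, ys = np.meshgrid(np.arange(n_side) * spacing, np.arange(n_side) * spacing)
    n = n_side * n_side
    coords = []
    for z in (+gap / 2, -gap / 2):
        coords.append(np.column_stack([xs.ravel(), ys.ravel(),
                                       np.full(n, z + 10.0)]))
    coords = np.vstack(coords)
    return mc.Frame(
        coords=coords,
        bead_kind=np.array(["lipid_marker"] * (2 * n), dtype=object),
        lipid_type=np.array(["DOPC"] * (2 * n), dtype=object),
        molecule_id=np.arange(2 * n),
        box=mc.Box([n_side * spacing, n_side * spacing, 20.0]),
    )
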