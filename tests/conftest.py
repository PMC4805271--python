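import numpy as np
import pytest

from confkeys import enm_core, structio, synthdata


def make_ca(coords, res_names=None, bfactors=None, chain="A"):
    """Bare CaStructure from a coordinate array (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return structio.CaStructure(
        chain_ids=np.array([chain] * n, dtype=object),
        res_numbers=np.arange(1, n + 1),
        icodes=np.array([""] * n, dtype=object),
        res_names=np.array(res_names if res_names is not None else ["ALA"] * n,
                           dtype=object),
        coords=coords,
        bfactors=np.ones(n) if bfactors is None else np.asarray(bfactors, float),
    )


def copy_with_coords(structure, coords):
    return structio.CaStructure(
        chain_ids=structure.chain_ids.copy(),
        res_numbers=structure.res_numbers.copy(),
        icodes=structure.icodes.copy(),
        res_names=structure.res_names.copy(),
        coords=np.asarray(coords, dtype=float),
        bfactors=structure.bfactors.copy(),
    )


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@pytest.fixture(scope="session")
def triangle():
    """Equilateral triangle of unit springs: 6 null + 3 internal modes."""
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                       [0.5, np.sqrt(3) / 2, 0.0]])
    s = make_ca(coords)
    springs = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)]
    model = enm_core.build_hessian(s, springs)
    return s, springs, model


@pytest.fixture(scope="session")
def two_domain():
    """Seeded two-domain fixture with its ENM at r_c = 10 Å."""
    spec = synthdata.FixtureSpec(seed=7, n_residues=60)
    s, truth = synthdata.make_structure(spec)
    model, modes = enm_core.build_enm(s, r_c=10.0)
    return s, truth, model, modes
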