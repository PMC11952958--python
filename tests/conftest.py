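import numpy as np
import pytest

from oligoscope import synth
from oligoscope.structio import StructureModel


@pytest.fixture(scope="session")
def fixture_structure():
    """Two-chain compact Cα fixture, 60 residues per chain."""
    return synth.gen_fixture_structure(n_residues=60, n_chains=2, seed=11)


@pytest.fixture(scope="session")
def sphere_curve_noisy():
    """Noisy sphere (R=50 Å) curve with its truth record."""
    return synth.gen_curve("sphere", {"radius": 50.0}, seed=21)


@pytest.fixture()
def toy_p21_crystal():
    """One-atom P2₁-like crystal: identity plus (-x, y+1/2, -z)."""
    ops = [(np.eye(3), np.zeros(3)),
           (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0]))]
    return StructureModel(
        chain=np.array(["A"]),
        resnum=np.array([1]),
        resname=np.array(["ALA"]),
        atom_name=np.array(["CA"]),
        element=np.array(["C"]),
        xyz=np.array([[1.0, 2.0, 3.0]]),
        occupancy=np.ones(1),
        cell=(20.0, 30.0, 40.0, 90.0, 90.0, 90.0),
        symmetry_ops=ops,
    )


def random_model(rng, n=50, scale=30.0):
    return StructureModel(
        chain=np.array(["A"] * n),
        resnum=np.arange(1, n + 1),
        resname=np.array(["ALA"] * n),
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        xyz=rng.uniform(-scale, scale, (n, 3)),
        occupancy=np.ones(n),
    )
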