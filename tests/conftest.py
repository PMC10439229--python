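import numpy as np
import pytest

from mhcgroove.structure_io import PeptideMap
from mhcgroove.synthetic import ScaffoldSpec, make_scaffold


@pytest.fixture(scope="session")
def default_scaffold():
    """One default groove+peptide scaffold with its ground-truth ledger."""
    return make_scaffold(ScaffoldSpec(geometry_seed=7))


@pytest.fixture(scope="session")
def scaffold(default_scaffold):
    return default_scaffold[0]


@pytest.fixture(scope="session")
def ledger(default_scaffold):
    return default_scaffold[1]


@pytest.fixture(scope="session")
def peptide_map(ledger):
    return PeptideMap(chain_id=ledger["peptide_chain_id"],
                      p1_number=ledger["p1_number"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2 ** 31)))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


def apply_rigid(structure, R, t):
    s = structure.copy()
    s.set_coords(s.coords() @ R.T + t)
    return s
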