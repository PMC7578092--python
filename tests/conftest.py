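import numpy as np
import pytest

from navrin.rin import build_rin
from navrin.structure_io import read_pdb
from navrin.synthetic_fixtures import make_helix_pdb


@pytest.fixture(scope="session")
def helix_pdb_path(tmp_path_factory):
    """Ideal 20-residue poly-alanine alpha-helix (phi=-57, psi=-47)."""
    path = tmp_path_factory.mktemp("fixtures") / "helix.pdb"
    make_helix_pdb(20, phi=-57.0, psi=-47.0, seed=0, path=path)
    return path


@pytest.fixture(scope="session")
def helix_structure(helix_pdb_path):
    return read_pdb(helix_pdb_path)


@pytest.fixture(scope="session")
def helix_rin(helix_structure):
    return build_rin(helix_structure)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
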