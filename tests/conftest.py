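import numpy as np
import pytest

from nucleomd.fixtures import make_fixture
from nucleomd.params import ForceFieldParameters


@pytest.fixture(scope="session")
def params():
    return ForceFieldParameters.default(salt_mM=100.0)


@pytest.fixture(scope="session")
def dimer(params):
    return make_fixture("harmonic-dimer", params)


@pytest.fixture(scope="session")
def mini_protein(params):
    return make_fixture("mini-protein", params)


@pytest.fixture(scope="session")
def duplex(params):
    return make_fixture("duplex-10bp", params)


@pytest.fixture(scope="session")
def wrapped_arc(params):
    return make_fixture("wrapped-arc", params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 12.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 11.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 11.50           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00 13.00           C
ATOM      6  N   LYS A   2       3.332   1.536   0.000  1.00 10.50           N
ATOM      7  CA  LYS A   2       3.989   2.839   0.000  1.00 12.50           C
ATOM      8  C   LYS A   2       5.504   2.694   0.000  1.00 11.00           C
ATOM      9  O   LYS A   2       6.030   1.580   0.000  1.00 11.00           O
ATOM     10  N   GLU A   3       6.200   3.824   0.000  1.00 10.00           N
ATOM     11  CA  GLU A   3       7.654   3.833   0.000  1.00 14.00           C
ATOM     12  C   GLU A   3       8.230   5.243   0.000  1.00 12.00           C
END
"""

MISSING_CA_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00 10.00           N
ATOM      3  C   GLY A   2       4.800   1.000   0.000  1.00 10.00           C
ATOM      4  CA  GLY A   3       7.600   0.000   0.000  1.00 10.00           C
END
"""


@pytest.fixture()
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture()
def missing_ca_pdb(tmp_path):
    path = tmp_path / "noca.pdb"
    path.write_text(MISSING_CA_PDB)
    return path
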