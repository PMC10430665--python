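import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles module

from gpcrscreen.synthetic import LibrarySpec, make_labeled_library


@pytest.fixture(scope="session")
def library():
    """The default-condition two-class library (50/class, 5 poses x 3 states)."""
    return make_labeled_library(LibrarySpec(seed=7))


@pytest.fixture(scope="session")
def small_library():
    """A faster library for tests that retrain repeatedly."""
    return make_labeled_library(LibrarySpec(n_per_class=12, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


MINIMAL_PDB = """\
ATOM      1  N   ALA A  10      -1.200   0.900   0.000  1.00  0.00           N
ATOM      2  CA  ALA A  10       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A  10       1.300   0.600   0.000  1.00  0.00           C
ATOM      4  O   ALA A  10       1.500   1.800   0.000  1.00  0.00           O
ATOM      5  CB  ALA A  10       0.000  -1.500   0.000  1.00  0.00           C
ATOM      6  N   SER A  11       8.800   0.900   5.000  1.00  0.00           N
ATOM      7  CA  SER A  11      10.000   0.000   5.000  1.00  0.00           C
ATOM      8  C   SER A  11      11.300   0.600   5.000  1.00  0.00           C
ATOM      9  O   SER A  11      11.500   1.800   5.000  1.00  0.00           O
ATOM     10  CB  SER A  11      10.000  -1.500   5.000  1.00  0.00           C
ATOM     11  OG  SER A  11      10.000  -2.900   5.000  1.00  0.00           O
HETATM   12  O   HOH A 201       3.000   3.000   3.000  1.00  0.00           O
HETATM   13  C1  LIG A 301       5.000   5.000   5.000  1.00  0.00           C
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p
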