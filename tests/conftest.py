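import numpy as np
import pytest

from deepevo import synthdata
from deepevo.seqio import SequenceRecord


@pytest.fixture(scope="session")
def family():
    """The default desk-scale synthetic family (records, truth, ogt)."""
    return synthdata.default_family(seed=7)


@pytest.fixture(scope="session")
def family_records(family):
    return family[0]


@pytest.fixture(scope="session")
def family_truth(family):
    return family[1]


@pytest.fixture(scope="session")
def family_ogt(family):
    return family[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_protein(rng, length: int, rid: str = "x") -> SequenceRecord:
    from deepevo.seqio import AMINO_ACIDS

    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return SequenceRecord(rid, seq)


# ---------------------------------------------------------------------------
# A hand-written PDB fixture: three residues (Lys, Glu, Ala) of chain A with
# CA atoms on the x axis and charged side-chain atoms at controlled
# distances (Lys NZ at 3.5 A from Glu OE1).
# ---------------------------------------------------------------------------

THREE_RESIDUE_PDB = """\
ATOM      1  N   LYS A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  LYS A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  NZ  LYS A   1       0.000   3.000   0.000  1.00  0.00           N
ATOM      4  N   GLU A   2       4.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLU A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      6  OE1 GLU A   2       3.500   3.000   0.000  1.00  0.00           O
ATOM      7  OE2 GLU A   2       8.000   3.000   0.000  1.00  0.00           O
ATOM      8  N   ALA A   3      19.000   0.000   0.000  1.00  0.00           N
ATOM      9  CA  ALA A   3      20.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


ALTLOC_PDB = """\
ATOM      1  N   LYS A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ALYS A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BLYS A   1       9.000   0.000   0.000  0.60  0.00           C
ATOM      4  NZ  LYS A   1       0.000   3.000   0.000  1.00  0.00           N
END
"""


@pytest.fixture()
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
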