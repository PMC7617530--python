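"""Shared fixtures: small structure files and synthetic models."""

import numpy as np
import pytest

from oncostruct import SyntheticSpec, generate_chain

# A 3-residue single-chain peptide with full backbone atoms; B-factors
# chosen distinct so pass-through can be asserted exactly.
THREE_RESIDUE_PDB = """\
REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 91.20           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 91.20           C
ATOM      3  C   ALA A   1      12.685   7.182  -5.033  1.00 91.20           C
ATOM      4  O   ALA A   1      13.339   7.378  -6.011  1.00 91.20           O
ATOM      5  CB  ALA A   1      12.251   4.690  -4.916  1.00 91.20           C
ATOM      6  N   GLY A   2      12.831   7.825  -3.876  1.00 45.00           N
ATOM      7  CA  GLY A   2      13.794   8.903  -3.709  1.00 45.00           C
ATOM      8  C   GLY A   2      13.193  10.216  -4.190  1.00 45.00           C
ATOM      9  O   GLY A   2      12.002  10.441  -3.983  1.00 45.00           O
ATOM     10  N   SER A   3      14.024  11.098  -4.738  1.00 88.00           N
ATOM     11  CA  SER A   3      13.601  12.413  -5.215  1.00 88.00           C
ATOM     12  C   SER A   3      14.365  13.532  -4.520  1.00 88.00           C
ATOM     13  O   SER A   3      15.583  13.446  -4.357  1.00 88.00           O
ATOM     14  OG  SER A   3      12.212  12.632  -5.044  1.00 88.00           O
TER
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00 10.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00 10.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def hetatm_only_pdb(tmp_path):
    path = tmp_path / "waters.pdb"
    path.write_text(HETATM_ONLY_PDB)
    return path


@pytest.fixture
def line_coords():
    """Five Cα positions on a line at 3.8 Å spacing."""
    coords = np.zeros((5, 3))
    coords[:, 0] = 3.8 * np.arange(5)
    return coords


@pytest.fixture(scope="session")
def compact_model():
    """One deterministic 200-residue compact-walk model, shared."""
    return generate_chain(SyntheticSpec(n_residues=200, seed=42), "compact200")
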