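"""Shared fixtures: tiny hand-written PDB files and toy structure builders."""
import numpy as np
import pytest

from structcons.io import ResidueRecord, StructureModel

# three-residue Ala-Cys-Asp chain with CA-only coordinates and B-factors
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 90.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 90.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 90.00           C
ATOM      4  O   ALA A   1       1.400   2.400   0.300  1.00 90.00           O
ATOM      5  N   CYS A   2       3.300   1.500   0.100  1.00 85.00           N
ATOM      6  CA  CYS A   2       4.100   2.700   0.300  1.00 85.00           C
ATOM      7  C   CYS A   2       5.500   2.300   0.700  1.00 85.00           C
ATOM      8  O   CYS A   2       5.800   1.100   0.800  1.00 85.00           O
ATOM      9  N   ASP A   3       6.400   3.300   0.900  1.00 70.00           N
ATOM     10  CA  ASP A   3       7.800   3.100   1.300  1.00 70.00           C
ATOM     11  C   ASP A   3       8.500   4.400   1.700  1.00 70.00           C
ATOM     12  O   ASP A   3       8.000   5.500   1.500  1.00 70.00           O
TER
END
"""

# as above but residue 2 lacks a CA atom
MISSING_CA_PDB = """\
ATOM      1  CA  ALA A   1       1.458   0.000   0.000  1.00 90.00           C
ATOM      2  N   CYS A   2       3.300   1.500   0.100  1.00 85.00           N
ATOM      3  C   CYS A   2       5.500   2.300   0.700  1.00 85.00           C
ATOM      4  CA  ASP A   3       7.800   3.100   1.300  1.00 70.00           C
TER
END
"""

# chain with a ligand (heteroatom group) and a water to be discarded
LIGAND_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 90.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 90.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00 90.00           C
HETATM    4  C1  LIG A 101       0.000   3.000   0.000  1.00 50.00           C
HETATM    5  O   HOH A 201      20.000  20.000  20.000  1.00 30.00           O
TER
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def missing_ca_pdb(tmp_path):
    p = tmp_path / "noca.pdb"
    p.write_text(MISSING_CA_PDB)
    return p


@pytest.fixture
def ligand_pdb(tmp_path):
    p = tmp_path / "lig.pdb"
    p.write_text(LIGAND_PDB)
    return p


def make_ca_model(sequence, coords, structure_id="toy", plddt=None):
    """CA-only StructureModel from a sequence and (n, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    residues = []
    for i, (aa, xyz) in enumerate(zip(sequence, coords)):
        residues.append(ResidueRecord(
            "A", i + 1, aa, [("CA", "C", np.array(xyz, dtype=float))],
            plddt=None if plddt is None else float(plddt[i]),
            author_seq_id=i + 1))
    return StructureModel(structure_id, residues)


def straight_chain(sequence, spacing=3.8, **kw):
    """Residues on a line, consecutive CA ``spacing`` apart."""
    n = len(sequence)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return make_ca_model(sequence, coords, **kw)


@pytest.fixture(scope="session")
def toy_fold():
    from structcons.synthetic import build_toy_fold

    return build_toy_fold(seed=11)


@pytest.fixture(scope="session")
def small_pool():
    """Five planted-pocket ancestors shared across expensive tests."""
    from structcons.experiments import ancestor_pool

    return ancestor_pool(5, base_seed=424)
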