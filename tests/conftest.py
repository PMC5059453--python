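import numpy as np
import pytest

from ubrec.structure import Atom, Structure, SymOp, UnitCell

# Table-1-style monoclinic C2 cell used for orthogonalization round-trips
MONOCLINIC_CELL = UnitCell(107.29, 49.70, 81.33, 90.0, 130.55, 90.0)


THREE_ATOM_PDB = """\
CRYST1  107.290   49.700   81.330  90.00 130.55  90.00 C 1 2 1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.715   7.124  -4.880  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.500   0.000   0.000  0.30  0.00           C
ATOM      3  CA BSER A   1       1.600   0.100   0.000  0.70  0.00           C
ATOM      4  C   SER A   1       2.200   1.300   0.000  1.00  0.00           C
ATOM      5  O   HOH W 101       9.000   9.000   9.000  1.00  0.00           O
ATOM      6  H   SER A   1       0.300  -0.900   0.000  1.00  0.00           H
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_chain(coords, chain="A", resname="GLY", name="CA", element="C",
               start_serial=1, one_res_per_atom=True):
    atoms = []
    for i, p in enumerate(np.atleast_2d(coords)):
        atoms.append(Atom(serial=start_serial + i, name=name, element=element,
                          resname=resname, resseq=i + 1 if one_res_per_atom else 1,
                          chain=chain, xyz=tuple(map(float, p))))
    return atoms


def two_chain_structure(coords_a, coords_b, cell=None):
    atoms = make_chain(coords_a, "A") + make_chain(coords_b, "B",
                                                   start_serial=len(coords_a) + 1)
    return Structure(atoms, cell=cell,
                     symops=[SymOp.identity()] if cell else [], label="toy",
                     spacegroup="P 1" if cell else "")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
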