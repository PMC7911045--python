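import numpy as np
import pytest

from scaffoldsmith.structure_model import Atom, Residue, StructureModel


def pdb_line(serial, name, resname, chain, num, x, y, z, occ=1.0, b=0.0,
             element=None, altloc=" "):
    element = element or name[0]
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {nm:<4s}"[:16] + f"{altloc}{resname:>3s} {chain}"
            f"{num:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


GLY_ALA_PDB = "\n".join([
    "REMARK   2 RESOLUTION.    1.80 ANGSTROMS.",
    pdb_line(1, "N", "GLY", "A", 1, -0.525, 1.362, 0.000),
    pdb_line(2, "CA", "GLY", "A", 1, 0.000, 0.000, 0.000, element="C"),
    pdb_line(3, "C", "GLY", "A", 1, 1.520, 0.000, 0.000, element="C"),
    pdb_line(4, "O", "GLY", "A", 1, 2.197, 1.024, 0.000),
    pdb_line(5, "N", "ALA", "A", 2, 2.100, -1.200, 0.000),
    pdb_line(6, "CA", "ALA", "A", 2, 3.550, -1.350, 0.000, element="C"),
    pdb_line(7, "C", "ALA", "A", 2, 4.200, -0.100, 0.600, element="C"),
    pdb_line(8, "O", "ALA", "A", 2, 5.400, 0.100, 0.500),
    pdb_line(9, "CB", "ALA", "A", 2, 4.100, -2.600, 0.700, element="C"),
    "TER",
    "END",
]) + "\n"

ALTLOC_PDB = "\n".join([
    pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
    pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, element="C"),
    pdb_line(3, "C", "ALA", "A", 1, 2.5, 1.0, 0.0, element="C"),
    pdb_line(4, "O", "ALA", "A", 1, 3.5, 1.0, 0.5),
    pdb_line(5, "CB", "ALA", "A", 1, 2.0, -1.0, 0.0, occ=0.60, element="C",
             altloc="A"),
    pdb_line(6, "CB", "ALA", "A", 1, 9.0, -1.0, 0.0, occ=0.40, element="C",
             altloc="B"),
    "TER",
    "END",
]) + "\n"


@pytest.fixture
def gly_ala_pdb(tmp_path):
    path = tmp_path / "gly_ala.pdb"
    path.write_text(GLY_ALA_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def single_atom_model(element="C", name="CA", aa="A"):
    atom = Atom(name, element, np.zeros(3))
    res = Residue("A", 1, "", aa, [atom])
    return StructureModel("TEST", {"A": [res]})


def point_model(coords, aa="A", atom_name="CA"):
    """One single-atom residue per coordinate; residues numbered 1..n."""
    residues = [
        Residue("A", i + 1, "", aa, [Atom(atom_name, "C", np.asarray(c, float))])
        for i, c in enumerate(coords)
    ]
    return StructureModel("PTS", {"A": residues})
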