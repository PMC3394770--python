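import pytest

from lectinkit import FixtureSpec, make_toy_crystal

#: Designed binding-pocket contacts: ligand hydroxyl/ring oxygens paired with
#: successive backbone amides at sugar-pocket-like distances.
POCKET_CONTACTS = [("O3", 3.1), ("O1", 3.4), ("O6", 3.2),
                   ("O5", 2.9), ("O2", 3.0), ("O4", 3.3)]


@pytest.fixture(scope="session")
def pocket_crystal():
    """Toy crystal with a designed sugar pocket, a methyl-pi probe above a
    tryptophan indole, and a metal site with five coordinating waters."""
    return make_toy_crystal(FixtureSpec(kind="toy_crystal", seed=7, parameters={
        "hbond_contacts": POCKET_CONTACTS,
        "me_pi_distance": 3.8,
        "metal_waters": 5,
    }))


@pytest.fixture(scope="session")
def dimer_crystal():
    """Chain whose (x,-y,-z) mate in C222(1) touches at a designed 3.5 A gap."""
    return make_toy_crystal(FixtureSpec(kind="toy_crystal", seed=3, parameters={
        "n_residues": 8,
        "symmetry_contact": {"op": "X,-Y,-Z", "distance": 3.5},
    }))


@pytest.fixture(scope="session")
def tetramer_crystal():
    """Mini-chain near the I222 dyad intersection: its three rotational mates
    all touch, mimicking a 222-symmetric tetramer in the crystal."""
    return make_toy_crystal(FixtureSpec(kind="toy_crystal", seed=5, parameters={
        "n_residues": 2,
        "origin": (1.5, 1.8, 1.2),
        "space_group": "I222",
    }))


MINI_PDB = """\
CRYST1   87.500  139.500  189.900  90.00  90.00  90.00 I 2 2 2        1
ATOM      1  N   GLY A   1      10.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  GLY A   1      11.200   1.000   0.000  1.00 21.50           C
ATOM      3  C   GLY A   1      12.400   0.300   0.000  1.00 19.00           C
END
"""


@pytest.fixture()
def mini_pdb_text():
    return MINI_PDB
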