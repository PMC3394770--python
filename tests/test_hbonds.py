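"""Contact geometry: hydrogen bonds, methyl-pi, metal coordination."""
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lectinkit.hbond_geometry import (
    DEFAULT_DICTIONARY, contact_table, find_hbonds, find_me_pi,
    find_metal_coordination,
)
from lectinkit.structure_io import AtomRecord


def _atom(serial, name, element, resname, resnum, pos, chain="A", hetero=False):
    return AtomRecord(serial, name, element, resname, resnum, chain,
                      np.array(pos, dtype=float), is_hetero=hetero)


def _phe_ring(resnum=10, center=(0.0, 0.0, 0.0), chain="A"):
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for i, name in enumerate(names):
        ang = math.radians(60 * i)
        pos = np.array(center) + 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
        atoms.append(_atom(50 + i, name, "C", "PHE", resnum, pos, chain=chain))
    return atoms


class TestFindHbonds:
    def test_backbone_amide_to_ring_oxygen(self):
        donor = _atom(1, "N", "N", "GLY", 1, (0, 0, 0))
        acceptor = _atom(2, "O5", "O", "MPY", 201, (2.9, 0, 0), hetero=True)
        records = find_hbonds([donor], [acceptor])
        assert len(records) == 1
        assert records[0].distance == pytest.approx(2.9)
        assert records[0].atom_1.label == "Gly1N"
        assert records[0].atom_2.label == "Mpy201O5"

    def test_carbons_never_bond(self):
        a = _atom(1, "CA", "C", "GLY", 1, (0, 0, 0))
        b = _atom(2, "C1", "C", "MPY", 201, (2.8, 0, 0), hetero=True)
        assert find_hbonds([a], [b]) == []

    def test_acceptor_acceptor_pair_excluded(self):
        # ring O5 accepts only, so it cannot pair with a backbone carbonyl
        a = _atom(1, "O", "O", "GLY", 1, (0, 0, 0))
        b = _atom(2, "O5", "O", "MPY", 201, (2.9, 0, 0), hetero=True)
        assert find_hbonds([a], [b]) == []

    def test_monotone_in_cutoff(self, pocket_crystal):
        protein = pocket_crystal.protein_atoms
        ligand = pocket_crystal.ligand_atoms
        previous: set = set()
        for cutoff in (2.8, 3.1, 3.5, 4.0):
            found = {r.signature for r in find_hbonds(protein, ligand, cutoff=cutoff)}
            assert previous <= found
            previous = found

    def test_matches_brute_force_oracle(self, pocket_crystal):
        protein = pocket_crystal.protein_atoms
        ligand = pocket_crystal.ligand_atoms
        cutoff = 3.5
        fast = {r.signature for r in find_hbonds(protein, ligand, cutoff=cutoff)}

        def polar(atoms):
            tagged = {}
            for a in atoms:
                res = [x for x in atoms if (x.chain_id, x.residue_number) ==
                       (a.chain_id, a.residue_number)]
                roles = DEFAULT_DICTIONARY.resolve(a.residue_name, {x.name for x in res})
                if roles is None:
                    continue
                donors, acceptors = roles
                tagged[id(a)] = (a, a.name in donors, a.name in acceptors)
            return list(tagged.values())

        slow = set()
        for a, ad, aa in polar(protein):
            for b, bd, ba in polar(ligand):
                if a.chain_id == b.chain_id and abs(a.residue_number - b.residue_number) <= 1:
                    continue
                d = float(np.linalg.norm(a.position - b.position))
                if d <= cutoff and ((ad and ba) or (aa and bd)):
                    from lectinkit.hbond_geometry import ContactRecord, QualifiedAtom
                    slow.add(ContactRecord("hbond", QualifiedAtom.of(a),
                                           QualifiedAtom.of(b), d).signature)
        assert fast == slow

    def test_invariant_under_rigid_motion(self, pocket_crystal):
        protein = pocket_crystal.protein_atoms
        ligand = pocket_crystal.ligand_atoms
        before = find_hbonds(protein, ligand)
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 113.0], degrees=True)
        shift = np.array([12.3, -4.5, 8.9])

        def moved(atoms):
            return [a.copy_with_position(rot.apply(a.position) + shift) for a in atoms]

        after = find_hbonds(moved(protein), moved(ligand))
        assert len(before) == len(after)
        for x, y in zip(before, after):
            assert (x.atom_1, x.atom_2) == (y.atom_1, y.atom_2)
            assert x.distance == pytest.approx(y.distance, abs=1e-6)

    def test_overlapping_selections_rejected(self):
        a = _atom(1, "N", "N", "GLY", 1, (0, 0, 0))
        with pytest.raises(ValueError, match="disjoint"):
            find_hbonds([a], [a])

    def test_unknown_residue_warned_and_skipped(self):
        a = _atom(1, "N", "N", "GLY", 1, (0, 0, 0))
        b = _atom(2, "O9", "O", "QQQ", 5, (2.9, 0, 0), hetero=True)
        with pytest.warns(UserWarning, match="QQQ"):
            assert find_hbonds([a], [b]) == []


class TestFindMePi:
    def test_carbon_above_ring_is_contact(self):
        ring = _phe_ring()
        probe = _atom(99, "C7", "C", "MPY", 201, (0, 0, 3.8), hetero=True)
        records = find_me_pi([probe], ring)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.8)
        assert records[0].extra == "ring6"

    def test_in_plane_carbon_fails_elevation_filter(self):
        ring = _phe_ring()
        probe = _atom(99, "C7", "C", "MPY", 201, (3.8, 0, 0), hetero=True)
        assert find_me_pi([probe], ring) == []

    def test_beyond_cutoff_no_contact(self):
        ring = _phe_ring()
        probe = _atom(99, "C7", "C", "MPY", 201, (0, 0, 5.0), hetero=True)
        assert find_me_pi([probe], ring) == []

    def test_trp_contributes_both_rings(self, pocket_crystal):
        # designed probe sits over the six-ring only
        ligand = pocket_crystal.ligand_atoms
        probe = [a for a in ligand if a.name == "C7"]
        records = find_me_pi(probe, pocket_crystal.protein_atoms)
        assert [r.extra for r in records] == ["ring6"]


class TestMetalCoordination:
    def test_five_oxygens_give_cn5(self):
        metal = _atom(1, "CD", "Cd", "CD", 301, (0, 0, 0), hetero=True)
        waters = [_atom(i + 2, "O", "O", "HOH", 302 + i,
                        2.3 * np.array(d), hetero=True)
                  for i, d in enumerate([(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                         (0, -1, 0), (0, 0, 1)])]
        records = find_metal_coordination([metal] + waters)
        assert len(records) == 5
        assert {r.extra for r in records} == {"CN=5"}

    def test_distant_oxygen_not_coordinating(self):
        metal = _atom(1, "CD", "Cd", "CD", 301, (0, 0, 0), hetero=True)
        o = _atom(2, "O", "O", "HOH", 302, (4.0, 0, 0), hetero=True)
        assert find_metal_coordination([metal, o], cutoff=3.0) == []

    def test_carbon_never_coordinates(self):
        metal = _atom(1, "CD", "Cd", "CD", 301, (0, 0, 0), hetero=True)
        c = _atom(2, "C1", "C", "MPY", 201, (2.3, 0, 0), hetero=True)
        assert find_metal_coordination([metal, c]) == []


class TestContactTable:
    def test_empty_input_header_only(self):
        df = contact_table([])
        assert df.empty

    def test_single_record_single_cell(self):
        donor = _atom(1, "N", "N", "GLY", 21, (0, 0, 0))
        acceptor = _atom(2, "O3", "O", "MPY", 201, (3.1, 0, 0), hetero=True)
        df = contact_table(find_hbonds([donor], [acceptor]))
        assert df.loc["Gly21N", "contacts"] == "Mpy201O3, 3.1 Å"

    def test_multi_complex_layout(self, pocket_crystal):
        records = find_hbonds(pocket_crystal.protein_atoms, pocket_crystal.ligand_atoms)
        df = contact_table({"complex_1": records, "complex_2": records[:2]})
        assert list(df.columns) == ["complex_1", "complex_2"]
        assert (df["complex_2"] == "-").sum() == len(records) - 2
        tsv = df.to_csv(sep="\t")
        assert tsv.startswith("protein_atom\t")
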