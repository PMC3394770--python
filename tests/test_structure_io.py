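"""PDB round-trips, space-group tables and cell arithmetic, with gemmi as the
independent crystallographic oracle."""
import math

import gemmi
import numpy as np
import pytest

from lectinkit import structure_io as sio
from lectinkit.structure_io import (
    PDBParseError, SpaceGroupError, UnitCell,
    cell_volume, chain_mass, matthews, parse_pdb, solvent_content,
    space_group_operators, summarize_crystal, write_pdb,
)


class TestParsePdb:
    def test_three_atom_fixture_round_trips(self, mini_pdb_text):
        s = parse_pdb(mini_pdb_text)
        assert len(s.atoms) == 3
        assert [a.name for a in s.atoms] == ["N", "CA", "C"]
        np.testing.assert_allclose(s.atoms[0].position, [10.0, 0.0, 0.0])
        s2 = parse_pdb(write_pdb(s))
        for a, b in zip(s.atoms, s2.atoms):
            np.testing.assert_allclose(a.position, b.position, atol=5e-4)
            assert (a.name, a.element, a.residue_name, a.residue_number,
                    a.chain_id, a.is_hetero) == \
                   (b.name, b.element, b.residue_name, b.residue_number,
                    b.chain_id, b.is_hetero)

    def test_cryst1_cell_and_operator_count(self, mini_pdb_text):
        s = parse_pdb(mini_pdb_text)
        assert s.cell == UnitCell(87.5, 139.5, 189.9, 90.0, 90.0, 90.0)
        assert len(s.operators) == 8  # I222: 4 rotations x body centering

    def test_blank_occupancy_names_line(self):
        bad = "ATOM      1  N   GLY A   1      10.000   0.000   0.000        20.00           N"
        with pytest.raises(PDBParseError, match="line 1.*occupancy"):
            parse_pdb(bad)

    def test_malformed_coordinate_names_line(self, mini_pdb_text):
        bad = mini_pdb_text.replace("  11.200", "  1x.200")
        with pytest.raises(PDBParseError, match="line 3"):
            parse_pdb(bad)

    def test_unknown_space_group_lists_supported(self):
        line = "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 41 21 2      8"
        with pytest.raises(SpaceGroupError, match="I 2 2 2"):
            parse_pdb(line)

    def test_missing_cryst1_refuses_cell_operations(self):
        s = parse_pdb("ATOM      1  N   GLY A   1      10.000   0.000   0.000  1.00 20.00           N")
        assert s.cell is None
        with pytest.raises(ValueError, match="cell required"):
            s.require_cell()

    def test_altloc_keeps_highest_occupancy_then_first_label(self):
        text = (
            "ATOM      1  CA BGLY A   1      10.000   0.000   0.000  0.30 20.00           C\n"
            "ATOM      2  CA AGLY A   1      11.000   0.000   0.000  0.70 20.00           C\n"
            "ATOM      3  CB AGLY A   2       0.000   0.000   0.000  0.50 20.00           C\n"
            "ATOM      4  CB BGLY A   2       1.000   0.000   0.000  0.50 20.00           C\n"
        )
        s = parse_pdb(text)
        assert len(s.atoms) == 2
        assert s.atoms[0].position[0] == 11.0   # higher occupancy wins
        assert s.atoms[1].altloc == "A"         # tie -> first label


class TestCellVolume:
    @pytest.mark.parametrize("cell,expected", [
        ((87.5, 139.5, 189.9, 90, 90, 90), 2_317_966.875),   # abc, orthorhombic
        ((1, 1, 1, 90, 90, 90), 1.0),
    ])
    def test_known_volumes(self, cell, expected):
        assert cell_volume(UnitCell(*cell)) == pytest.approx(expected, rel=1e-9)

    def test_monoclinic_equals_abc_sin_beta(self):
        # oracle: gemmi gives 297870.57 for this cell (= abc*sin(beta))
        cell = UnitCell(59.3, 83.7, 65.1, 90, 112.8, 90)
        assert cell_volume(cell) == pytest.approx(
            gemmi.UnitCell(59.3, 83.7, 65.1, 90, 112.8, 90).volume, rel=1e-12)
        assert cell_volume(cell) == pytest.approx(
            59.3 * 83.7 * 65.1 * math.sin(math.radians(112.8)), rel=1e-12)

    def test_agrees_with_orthogonalization_determinant(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c = rng.uniform(20, 200, 3)
            alpha, beta, gamma = rng.uniform(60, 120, 3)
            try:
                cell = UnitCell(a, b, c, alpha, beta, gamma)
            except ValueError:
                continue
            det = float(np.linalg.det(cell.orthogonalization_matrix))
            assert cell_volume(cell) == pytest.approx(det, rel=1e-6)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 179.9, 0.2, 0.2)


class TestMatthewsSolvent:
    def test_apo_cell_five_and_eight_chains(self):
        V = cell_volume(UnitCell(87.5, 139.5, 189.9, 90, 90, 90))
        assert matthews(V, 5 * 8, 16_510) == pytest.approx(3.51, abs=0.005)
        assert matthews(V, 8 * 8, 16_510) == pytest.approx(2.19, abs=0.005)

    def test_trivial_and_homogeneity(self):
        assert matthews(1000, 1, 1000) == 1.0
        assert matthews(2 * 1000, 2 * 1, 1000) == matthews(1000, 1, 1000)

    def test_zero_mass_errors(self):
        with pytest.raises(ValueError):
            matthews(1000, 1, 0)

    @pytest.mark.parametrize("vm,expected", [(3.51, 0.650), (2.21, 0.444)])
    def test_solvent_content_printed_values(self, vm, expected):
        assert solvent_content(vm) == pytest.approx(expected, abs=5e-4)

    def test_solvent_boundary_errors(self):
        with pytest.raises(ValueError, match="non-positive"):
            solvent_content(1.2284)

    def test_solvent_strictly_increasing(self):
        vms = np.linspace(1.3, 6.0, 50)
        vals = [solvent_content(v) for v in vms]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestChainMass:
    def test_free_glycine_and_dipeptide(self):
        assert chain_mass(["GLY"]) == pytest.approx(75.07)
        assert chain_mass(["GLY", "GLY"]) == pytest.approx(2 * 75.07 - 18.02)

    def test_unknown_residue_reported_and_excluded(self):
        with pytest.warns(UserWarning, match="XYZ"):
            mass = chain_mass(["GLY", "XYZ", "GLY"])
        assert mass == pytest.approx(2 * 75.07 - 18.02)

    def test_from_atom_records(self, pocket_crystal):
        protein = pocket_crystal.protein_atoms
        n_res = len({(a.chain_id, a.residue_number) for a in protein})
        expected = (19 * 75.07 + 204.23) - (n_res - 1) * 18.02
        assert chain_mass(protein) == pytest.approx(expected)


class TestSpaceGroups:
    @pytest.mark.parametrize("symbol,hm", [
        ("I222", "I 2 2 2"), ("C2221", "C 2 2 21"),
        ("P21", "P 1 21 1"), ("P212121", "P 21 21 21"), ("P1", "P 1"),
    ])
    def test_operator_sets_match_gemmi(self, symbol, hm):
        ours = {op.key(mod_lattice=True) for op in space_group_operators(symbol)}
        theirs = set()
        for op in gemmi.SpaceGroup(hm).operations():
            rot = tuple(int(x) for x in (np.array(op.rot) // 24).flat)
            tran = tuple(round((t / 24.0) % 1.0, 6) for t in op.tran)
            theirs.add((rot, tran))
        assert ours == theirs

    @pytest.mark.parametrize("symbol", ["I222", "C2221", "P21", "P212121"])
    def test_closure_under_composition_mod_lattice(self, symbol):
        ops = space_group_operators(symbol)
        keys = {op.key(mod_lattice=True) for op in ops}
        for a in ops:
            for b in ops:
                assert a.compose(b).key(mod_lattice=True) in keys


def test_summarize_crystal_uses_longest_chain(mini_pdb_text):
    summary = summarize_crystal(parse_pdb(mini_pdb_text))
    assert summary.multiplicity == 8
    assert summary.n_chains_asym == 1
    assert summary.monomer_mass == pytest.approx(75.07)
    assert summary.matthews == pytest.approx(
        2_317_966.875 / (8 * 75.07), rel=1e-9)
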