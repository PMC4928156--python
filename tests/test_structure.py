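"""Parsing, solvent accessibility, RSA classification, and interfaces."""

import io

import numpy as np
import pytest
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

from stabilis import (
    classify_accessibility,
    compute_sasa,
    interface_residues,
    parse_structure,
    relative_accessibility,
)
from stabilis._aa_data import MAX_ACC, VDW_DEFAULT_RADIUS, VDW_RADII
from stabilis.errors import InputError, ValidationError
from stabilis.structure import (
    AtomRecord,
    ResidueSite,
    Structure,
    apply_position_map,
    read_position_map,
    shrake_rupley_areas,
)
from stabilis.synthetic import add_occluder_shell, make_toy_structure, toy_pdb_text

from conftest import make_point_structure


def biopython_sasa(pdb_text, n_points=5000):
    """Independent dense-sampling oracle: Biopython's Shrake-Rupley."""
    radii = dict(VDW_RADII)
    radii.update({"H": VDW_DEFAULT_RADIUS, "D": VDW_DEFAULT_RADIUS})
    bs = PDBParser(QUIET=True).get_structure("oracle", io.StringIO(pdb_text))
    ShrakeRupley(probe_radius=1.4, n_points=n_points, radii_dict=radii).compute(
        bs, level="R"
    )
    return {
        (chain.id, res.id[1]): float(res.sasa)
        for chain in bs[0]
        for res in chain
    }


class TestParsing:
    def test_toy_helix_round_trip(self):
        s, _ = make_toy_structure(3)
        assert list(s.chains) == ["A"]
        assert len(s.chains["A"]) == 3
        assert [r.seq_pos for r in s.chains["A"]] == [1, 2, 3]
        assert all(r.aa == "A" and r.is_standard for r in s.chains["A"])

    def test_resolution_header_echo(self):
        s, _ = make_toy_structure(3, resolution=1.80)
        assert s.resolution == pytest.approx(1.80)
        s2, _ = make_toy_structure(3)
        assert s2.resolution is None

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.500   0.000   0.000  0.40  0.00           C\n"
            "ATOM      3  CA BALA A   1       1.600   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        s = parse_structure(text)
        ca = [a for a in s.chains["A"][0].atoms if a.name == "CA"]
        assert len(ca) == 1
        assert ca[0].coords[0] == pytest.approx(1.600)  # occupancy 0.60 wins

    def test_altloc_tie_broken_alphabetically(self):
        text = (
            "ATOM      1  CA AALA A   1       1.500   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       1.600   0.000   0.000  0.50  0.00           C\n"
            "END\n"
        )
        s = parse_structure(text)
        assert s.chains["A"][0].atoms[0].coords[0] == pytest.approx(1.500)

    def test_hetatm_excluded(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        s = parse_structure(text)
        assert len(s.chains["A"]) == 1

    def test_malformed_coordinate_line_names_line_number(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       bad_x   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(InputError, match="line 2"):
            parse_structure(text)

    def test_empty_model_errors(self):
        with pytest.raises(InputError):
            parse_structure("REMARK nothing here\nEND\n")

    def test_non_increasing_positions_rejected(self):
        text = (
            "ATOM      1  CA  ALA A   5       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   3       4.000   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(ValidationError):
            parse_structure(text)

    def test_position_map_renumbers(self):
        s, _ = make_toy_structure(3)
        mapping = read_position_map("A\t1\t101\nA\t2\t102\nA\t3\t103\n")
        apply_position_map(s, mapping)
        assert [r.seq_pos for r in s.chains["A"]] == [101, 102, 103]


class TestSasa:
    def test_free_glycine_matches_dense_oracle(self):
        text = toy_pdb_text(1, sequence="G")
        s = parse_structure(text)
        compute_sasa(s)
        oracle = biopython_sasa(text, n_points=5000)[("A", 1)]
        assert s.chains["A"][0].sasa == pytest.approx(oracle, rel=0.02)

    def test_per_residue_agreement_with_oracle_on_pentamer(self):
        text = toy_pdb_text(5, sequence="AGWLS")
        s = parse_structure(text)
        compute_sasa(s)
        oracle = biopython_sasa(text, n_points=5000)
        for res in s.chains["A"]:
            assert res.sasa == pytest.approx(oracle[("A", res.seq_pos)], rel=0.05)

    def test_enclosed_residue_is_buried(self):
        s, _ = make_toy_structure(1, sequence="G")
        shelled = add_occluder_shell(s, "A", 1, radius=5.0, n_shell=300)
        compute_sasa(shelled)
        assert shelled.get_residue("A", 1).sasa == pytest.approx(0.0, abs=1.0)

    def test_occlusion_reduces_interface_sasa(self, toy_complex):
        iso, cpx, _, _ = toy_complex
        for pos in (4, 5, 6):
            assert (
                cpx.get_residue("A", pos).sasa < iso.get_residue("A", pos).sasa
            )

    def test_total_sasa_monotone_in_probe_radius(self):
        s, _ = make_toy_structure(5)
        totals = []
        for probe in (0.0, 0.7, 1.4):
            compute_sasa(s, probe_radius=probe)
            totals.append(sum(r.sasa for r in s.chains["A"]))
        assert totals[0] < totals[1] < totals[2]

    def test_residue_without_heavy_atoms_errors(self):
        res = ResidueSite(
            chain_id="A",
            seq_pos=1,
            aa="A",
            atoms=[AtomRecord(name="H", element="H", coords=[0, 0, 0], is_hydrogen=True)],
        )
        s = Structure(id="x", assembly_kind="isolated_chain", chains={"A": [res]})
        with pytest.raises(InputError, match="A:1"):
            compute_sasa(s)

    def test_isolated_atom_area_is_analytic_sphere(self):
        # one C atom, probe 1.4: SASA must equal 4*pi*(1.87+1.4)^2 exactly
        areas = shrake_rupley_areas(np.zeros((1, 3)), np.array([1.87]))
        assert areas[0] == pytest.approx(4 * np.pi * 3.27**2, rel=1e-12)


class TestRsa:
    def _one_residue(self, sasa, aa="A"):
        res = ResidueSite(
            chain_id="A",
            seq_pos=1,
            aa=aa,
            atoms=[AtomRecord(name="CA", element="C", coords=[0, 0, 0])],
            sasa=sasa,
        )
        return Structure(id="x", assembly_kind="isolated_chain", chains={"A": [res]})

    @pytest.mark.parametrize(
        "sasa_factor, expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)]
    )
    def test_rsa_is_linear_in_sasa(self, sasa_factor, expected):
        s = self._one_residue(sasa_factor * MAX_ACC["A"])
        relative_accessibility(s)
        assert s.chains["A"][0].rsa == pytest.approx(expected)

    def test_rsa_above_one_clamped_with_raw_retained(self):
        s = self._one_residue(1.3 * MAX_ACC["A"])
        relative_accessibility(s)
        res = s.chains["A"][0]
        assert res.rsa == 1.0
        assert res.rsa_raw == pytest.approx(1.3)

    def test_nonstandard_residue_flagged_undefined(self):
        s = self._one_residue(50.0)
        s.chains["A"][0].aa = "X"
        s.chains["A"][0].is_standard = False
        relative_accessibility(s)
        assert s.chains["A"][0].rsa is None

    def test_missing_sasa_errors(self):
        s = self._one_residue(None)
        with pytest.raises(InputError):
            relative_accessibility(s)


class TestClassification:
    @pytest.mark.parametrize(
        "rsa, expected",
        [(0.20, "accessible"), (0.19, "buried"), (0.0, "buried"), (1.0, "accessible")],
    )
    def test_threshold_boundary(self, rsa, expected):
        assert classify_accessibility(rsa) == expected

    def test_undefined_rsa_errors(self):
        with pytest.raises(InputError):
            classify_accessibility(None)

    def test_monotone_threshold_function(self):
        grid = np.linspace(0, 1, 101)
        classes = [classify_accessibility(r) == "accessible" for r in grid]
        # once accessible, stays accessible
        assert classes == sorted(classes)


class TestInterface:
    def test_identity_input_gives_empty_set(self, helix9):
        s, _ = helix9
        assert interface_residues(s, s, "A") == set()

    def test_detects_exactly_the_downward_crossings(self, toy_complex):
        iso, cpx, _, _ = toy_complex
        expected = {
            r.seq_pos
            for r in iso.chains["A"]
            if r.rsa >= 0.2 and cpx.get_residue("A", r.seq_pos).rsa < 0.2
        }
        assert expected  # the cage fixture must create a real interface
        assert interface_residues(iso, cpx, "A") == expected

    def test_buried_in_both_not_returned(self):
        def one(rsa):
            res = ResidueSite(
                chain_id="A", seq_pos=1, aa="A",
                atoms=[AtomRecord(name="CA", element="C", coords=[0, 0, 0])],
                sasa=1.0, rsa=rsa, rsa_raw=rsa,
            )
            return Structure(id="x", assembly_kind="isolated_chain", chains={"A": [res]})

        assert interface_residues(one(0.10), one(0.05), "A") == set()
        assert interface_residues(one(0.50), one(0.10), "A") == {1}

    def test_missing_chain_errors(self, helix9):
        s, _ = helix9
        with pytest.raises(InputError, match="chain 'B'"):
            interface_residues(s, s, "B")

    def test_position_mismatch_lists_positions(self, helix9):
        s, _ = helix9
        other = make_point_structure([[0, 0, 0], [4, 0, 0]])
        for res in other.chains["A"]:
            res.sasa, res.rsa = 10.0, 0.1
        with pytest.raises(ValidationError, match="positions differ"):
            interface_residues(s, other, "A")
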