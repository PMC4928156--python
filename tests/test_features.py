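"""The nine-feature encoding: scales, profiles, contacts and assembly."""

import numpy as np
import pytest

from stabilis._aa_data import AA1
from stabilis.errors import InputError, ValidationError
from stabilis.features import (
    ContactPotential,
    FeatureVector,
    SequenceProfile,
    VariantSpec,
    blosum62_score,
    build_feature_vector,
    contact_energy_diff,
    contact_neighbors,
    kd_hydropathy,
    molecular_weight,
    mutability,
    profile_score_diff,
)
from stabilis.synthetic import add_occluder_shell, make_toy_structure

from conftest import make_point_structure, make_random_structure


class TestScales:
    def test_blosum62_canonical_entries(self):
        assert blosum62_score("A", "A") == 4
        assert blosum62_score("W", "G") == -2

    def test_blosum62_symmetry_all_pairs(self):
        for a in AA1:
            for b in AA1:
                assert blosum62_score(a, b) == blosum62_score(b, a)

    @pytest.mark.parametrize("aa, val", [("I", 4.5), ("R", -4.5), ("G", -0.4)])
    def test_kyte_doolittle_values(self, aa, val):
        assert kd_hydropathy(aa) == val

    def test_mutability_is_positive_with_dayhoff_anchors(self):
        vals = {aa: mutability(aa) for aa in AA1}
        assert all(v > 0 for v in vals.values())
        assert vals["A"] == 100          # Ala = 100 convention
        assert max(vals, key=vals.get) == "N"
        assert min(vals, key=vals.get) == "W"

    def test_molecular_weight_free_amino_acid(self):
        assert molecular_weight("G") == pytest.approx(75.07)
        assert max(AA1, key=molecular_weight) == "W"

    def test_isobaric_pairs(self):
        # mw(wt) == mw(mut) only for identity or the Leu/Ile pair
        equal_pairs = {
            frozenset((a, b))
            for a in AA1
            for b in AA1
            if a != b and molecular_weight(a) == molecular_weight(b)
        }
        assert equal_pairs == {frozenset(("L", "I"))}

    @pytest.mark.parametrize(
        "fn", [blosum62_score, kd_hydropathy, mutability, molecular_weight]
    )
    def test_nonstandard_amino_acid_rejected(self, fn):
        with pytest.raises(ValueError):
            fn("B") if fn is not blosum62_score else fn("B", "A")


class TestProfile:
    def test_uniform_profile_gives_zero(self):
        prof = SequenceProfile(np.ones((10, 20)))
        assert profile_score_diff(prof, VariantSpec("P", 3, "A", "W")) == 0.0

    def test_constructed_difference(self):
        scores = np.zeros((5, 20))
        scores[2, AA1.index("A")] = 2.0
        scores[2, AA1.index("W")] = -1.0
        prof = SequenceProfile(scores)
        assert profile_score_diff(prof, VariantSpec("P", 3, "A", "W")) == 3.0

    def test_synonymous_variant_gives_zero(self):
        prof = SequenceProfile(np.random.default_rng(0).normal(size=(5, 20)))
        assert profile_score_diff(prof, VariantSpec("P", 2, "A", "A")) == 0.0

    def test_position_outside_profile_errors(self):
        prof = SequenceProfile(np.zeros((3, 20)))
        with pytest.raises(InputError):
            profile_score_diff(prof, VariantSpec("P", 4, "A", "W"))

    def test_pseudo_profile_reduces_to_blosum_difference(self):
        seq = "MKTA"
        prof = SequenceProfile.pseudo_from_sequence(seq)
        assert prof.is_pseudo
        v = VariantSpec("P", 2, "K", "R")
        expected = blosum62_score("K", "K") - blosum62_score("K", "R")
        assert profile_score_diff(prof, v) == expected

    def test_tsv_round_trip(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(4, 20)).round(4)
        header = "\t".join(AA1)
        body = "\n".join("\t".join(f"{x:.4f}" for x in row) for row in scores)
        prof = SequenceProfile.from_tsv(header + "\n" + body)
        np.testing.assert_allclose(prof.scores, scores)


class TestContacts:
    @pytest.mark.parametrize(
        "distance, in_contact", [(4.9, True), (5.0, True), (5.1, False)]
    )
    def test_five_angstrom_cutoff_inclusive(self, distance, in_contact):
        s = make_point_structure([[0, 0, 0], [distance, 0, 0]])
        neighbours = contact_neighbors(s, "A", 1, cutoff=5.0)
        assert (len(neighbours) == 1) == in_contact

    def test_isolated_residue_has_no_neighbours(self):
        s = make_point_structure([[0, 0, 0], [50, 0, 0]])
        assert contact_neighbors(s, "A", 1) == []

    def test_missing_residue_errors(self):
        s = make_point_structure([[0, 0, 0]])
        with pytest.raises(InputError):
            contact_neighbors(s, "A", 99)

    def test_cross_chain_contacts_counted(self):
        s = make_point_structure([[0, 0, 0]])
        other = make_point_structure([[3, 0, 0]], chain_id="B")
        s.chains["B"] = other.chains["B"]
        assert len(contact_neighbors(s, "A", 1)) == 1

    def test_exclusion_window_drops_sequence_neighbours(self):
        s = make_point_structure([[0, 0, 0], [3, 0, 0], [4.5, 0, 0]])
        assert len(contact_neighbors(s, "A", 1)) == 2
        assert len(contact_neighbors(s, "A", 1, exclude_window=1)) == 1


class TestContactEnergy:
    def toy_potential(self, wt="A", mut="W"):
        """P(r, wt) = 1 and P(r, mut) = -1 for every r."""
        mat = np.zeros((20, 20))
        mat[:, AA1.index(wt)] = 1.0
        mat[AA1.index(wt), :] = 1.0
        mat[:, AA1.index(mut)] = -1.0
        mat[AA1.index(mut), :] = -1.0
        mat[AA1.index(wt), AA1.index(mut)] = 0.0  # keep symmetric
        mat[AA1.index(mut), AA1.index(wt)] = 0.0
        return ContactPotential(mat)

    def test_three_neighbours_toy_matrix(self):
        s = make_point_structure(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], aas=["G", "S", "T", "C"]
        )
        v = VariantSpec("P", 1, "A", "W")  # wt mismatch irrelevant here
        neighbours = contact_neighbors(s, "A", 1)
        assert len(neighbours) == 3
        # brute-force: each neighbour contributes P(r,A) - P(r,W) = 1 - (-1) = 2
        assert contact_energy_diff(self.toy_potential(), neighbours, v) == 6.0

    def test_synonymous_variant_is_exactly_zero(self):
        rng = np.random.default_rng(5)
        s = make_random_structure(rng)
        neighbours = contact_neighbors(s, "A", 1)
        pot = ContactPotential.default()
        v = VariantSpec("P", 1, "L", "L")
        assert contact_energy_diff(pot, neighbours, v) == 0.0

    def test_empty_neighbour_list_is_zero(self):
        assert contact_energy_diff(
            ContactPotential.default(), [], VariantSpec("P", 1, "A", "W")
        ) == 0.0

    def test_nonstandard_neighbour_skipped_with_warning(self, caplog):
        s = make_point_structure([[0, 0, 0], [3, 0, 0]], aas=["A", "X"])
        s.chains["A"][1].is_standard = False
        neighbours = contact_neighbors(s, "A", 1)
        with caplog.at_level("WARNING"):
            val = contact_energy_diff(
                ContactPotential.default(), neighbours, VariantSpec("P", 1, "A", "W")
            )
        assert val == 0.0
        assert "non-standard" in caplog.text

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_double_loop(self, seed):
        """Neighbour-list sum equals an all-pairs scan restricted to the cutoff."""
        rng = np.random.default_rng(seed)
        s = make_random_structure(rng, n_res=12, atoms_per_res=3)
        pot = ContactPotential.default()
        site = int(rng.integers(1, 13))
        v = VariantSpec("P", site, s.get_residue("A", site).aa, AA1[rng.integers(20)])

        target = s.get_residue("A", site)
        brute = 0.0
        for res in s.chains["A"]:
            if res is target:
                continue
            dmin = min(
                float(np.linalg.norm(a.coords - b.coords))
                for a in target.atoms
                for b in res.atoms
            )
            if dmin <= 5.0:
                brute += pot.energy(res.aa, v.wt) - pot.energy(res.aa, v.mut)
        neighbours = contact_neighbors(s, "A", site)
        assert contact_energy_diff(pot, neighbours, v) == brute  # bit-exact


class TestPotential:
    def test_default_is_symmetric_and_finite(self):
        pot = ContactPotential.default()
        assert np.allclose(pot.matrix, pot.matrix.T)
        assert np.all(np.isfinite(pot.matrix))

    def test_tsv_round_trip_labelled(self):
        pot = ContactPotential.default()
        header = "\t" + "\t".join(AA1)
        rows = [
            AA1[i] + "\t" + "\t".join(f"{x:.6f}" for x in pot.matrix[i])
            for i in range(20)
        ]
        again = ContactPotential.from_tsv(header + "\n" + "\n".join(rows))
        np.testing.assert_allclose(again.matrix, pot.matrix, atol=1e-6)

    def test_asymmetric_matrix_rejected(self):
        mat = np.zeros((20, 20))
        mat[0, 1] = 1.0
        with pytest.raises(InputError):
            ContactPotential(mat)


@pytest.fixture(scope="module")
def setup():
    seq = "AAAAGAAAA"
    s, _ = make_toy_structure(9, sequence=seq)
    prof = SequenceProfile.pseudo_from_sequence(seq)
    pot = ContactPotential.default()
    return seq, prof, s, pot


class TestFeatureVector:

    def test_components_match_independent_computation(self, setup):
        seq, prof, s, pot = setup
        v = VariantSpec("P", 5, "G", "W")
        fv = build_feature_vector(seq, prof, s, pot, v)
        assert fv.blosum62_score == blosum62_score("G", "W")
        assert fv.kd_wt == kd_hydropathy("G")
        assert fv.kd_mut == kd_hydropathy("W")
        assert fv.mutability_wt == mutability("G")
        assert fv.mw_wt == molecular_weight("G")
        assert fv.mw_mut == molecular_weight("W")
        assert fv.profile_score_diff == profile_score_diff(prof, v)
        assert fv.rsa_mut_site == s.get_residue("A", 5).rsa
        neighbours = contact_neighbors(s, "A", 5)
        assert fv.contact_energy_diff == contact_energy_diff(pot, neighbours, v)

    def test_synonymous_variant_collapses(self, setup):
        seq, prof, s, pot = setup
        fv = build_feature_vector(seq, prof, s, pot, VariantSpec("P", 5, "G", "G"))
        assert fv.blosum62_score == blosum62_score("G", "G")
        assert fv.profile_score_diff == 0.0
        assert fv.contact_energy_diff == 0.0

    def test_buried_site_has_low_rsa_feature(self, setup):
        seq, prof, _, pot = setup
        s, _ = make_toy_structure(9, sequence=seq)
        buried = add_occluder_shell(s, "A", 5, radius=6.0, n_shell=250)
        fv = build_feature_vector(seq, prof, buried, pot, VariantSpec("P", 5, "G", "A"),
                                  chain_id="A")
        assert fv.rsa_mut_site < 0.2

    def test_wild_type_mismatch_guards_numbering_drift(self, setup):
        seq, prof, s, pot = setup
        with pytest.raises(ValidationError):
            build_feature_vector(seq, prof, s, pot, VariantSpec("P", 5, "A", "W"))

    def test_antisymmetry_under_wt_mut_swap(self, setup):
        seq, prof, s, pot = setup
        v_fwd = VariantSpec("P", 5, "G", "W")
        fwd = build_feature_vector(seq, prof, s, pot, v_fwd)
        # reverse direction evaluated component-wise (the native structure
        # and sequence of the reverse variant are not constructible here,
        # so compare the swappable components directly)
        neighbours = contact_neighbors(s, "A", 5)
        rev_contact = contact_energy_diff(pot, neighbours, VariantSpec("P", 5, "W", "G"))
        assert rev_contact == -fwd.contact_energy_diff
        assert blosum62_score("W", "G") == fwd.blosum62_score

    def test_deterministic_bit_identical(self, setup):
        seq, prof, s, pot = setup
        v = VariantSpec("P", 3, "A", "K")
        a = build_feature_vector(seq, prof, s, pot, v).as_array()
        b = build_feature_vector(seq, prof, s, pot, v).as_array()
        assert np.array_equal(a, b)

    def test_rsa_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            FeatureVector(0, 0, 0, 100, 75, 75, 0, 1.5, 0)
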