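"""Four-term energy, null-model Z statistic and per-residue contributions."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from interolog3d import (
    ContactPair,
    TemplateInterface,
    build_null_model,
    build_profile,
    residue_contribution,
    score_candidate,
    score_cons,
    score_sim,
    score_special,
    score_vdw,
    self_alignment,
    total_score,
    z_value,
)
from interolog3d.matrices import (
    MatrixSet,
    PairScoringMatrix,
    count_pairs,
    derive_matrix_set,
)
from interolog3d.scoring import DegenerateModelError, _identity_alignment


def _single_pair_template(aa_a="W", aa_b="L", special="none",
                          classes=frozenset({"ss"})):
    return TemplateInterface(
        template_id="one", chain_a_id="A", chain_b_id="B",
        chain_a_seq=aa_a, chain_b_seq=aa_b,
        contact_residues_a=(1,), contact_residues_b=(1,),
        contact_pairs=[ContactPair(
            pos_a=1, pos_b=1, aa_a=aa_a, aa_b=aa_b, classes=classes,
            min_distance=4.0, special_bond=special,
        )],
    )


def _aln(template_seq, query_seq, chain="A", gap_positions=()):
    aln = _identity_alignment(chain, template_seq, query_seq)
    for p in gap_positions:
        del aln.pairs[p]
    return aln


class TestVdwTerm:
    def test_self_alignment_is_a_fixed_point(self, toy_template, toy_matrices):
        aln_a = _aln(toy_template.chain_a_seq, toy_template.chain_a_seq, "A")
        aln_b = _aln(toy_template.chain_b_seq, toy_template.chain_b_seq, "B")
        expected = 0.0
        for pair in toy_template.contact_pairs:
            if "ss" in pair.classes:
                expected += toy_matrices.ss_vdw.lookup(pair.aa_a, pair.aa_b)
            if "sb" in pair.classes:
                expected += toy_matrices.sb_vdw.lookup(pair.aa_a, pair.aa_b)
            if "bs" in pair.classes:
                expected += toy_matrices.sb_vdw.lookup(pair.aa_b, pair.aa_a)
        assert score_vdw(toy_template, aln_a, aln_b, toy_matrices) == \
            pytest.approx(expected)

    def test_candidate_difference_is_a_matrix_difference(self, toy_matrices):
        # template Cys-Phe contact; one candidate conserves, the other
        # substitutes the co-evolved Leu-Met pair
        t = _single_pair_template("C", "F")
        base = score_vdw(t, _aln("C", "C"), _aln("F", "F", "B"), toy_matrices)
        swapped = score_vdw(t, _aln("C", "L"), _aln("F", "M", "B"), toy_matrices)
        expected = toy_matrices.ss_vdw.lookup("L", "M") - \
            toy_matrices.ss_vdw.lookup("C", "F")
        assert swapped - base == pytest.approx(expected)

    def test_gapped_contact_position_contributes_zero(self, toy_template,
                                                      toy_matrices):
        aln_a = _aln(toy_template.chain_a_seq, toy_template.chain_a_seq, "A")
        aln_b = _aln(toy_template.chain_b_seq, toy_template.chain_b_seq, "B")
        full = score_vdw(toy_template, aln_a, aln_b, toy_matrices)
        pos = toy_template.contact_pairs[5].pos_a
        gapped_a = _aln(toy_template.chain_a_seq, toy_template.chain_a_seq,
                        "A", gap_positions=(pos,))
        partial = score_vdw(toy_template, gapped_a, aln_b, toy_matrices)
        lost = sum(
            toy_matrices.ss_vdw.lookup(p.aa_a, p.aa_b)
            for p in toy_template.contact_pairs
            if p.pos_a == pos and "ss" in p.classes
        )
        assert full - partial == pytest.approx(lost)

    def test_lower_matrix_value_never_increases_score(self, toy_matrices):
        t = _single_pair_template("L", "M")
        base = score_vdw(t, _aln("L", "L"), _aln("M", "M", "B"), toy_matrices)
        for x in "ACDEFGHIKLMNPQRSTVWY":
            other = score_vdw(t, _aln("L", x), _aln("M", "M", "B"),
                              toy_matrices)
            delta_matrix = toy_matrices.ss_vdw.lookup(x, "M") - \
                toy_matrices.ss_vdw.lookup("L", "M")
            if delta_matrix <= 0:
                assert other <= base + 1e-12


class TestSpecialTerm:
    def test_no_special_bonds_scores_zero(self, toy_matrices):
        t = _single_pair_template("K", "E", special="none")
        assert score_special(t, _aln("K", "K"), _aln("E", "E", "B"),
                             toy_matrices) == 0.0

    def test_conserved_salt_bridge_is_one_lookup(self):
        t = _single_pair_template("K", "E", special="salt_bridge")
        matrices, _ = derive_matrix_set([t])
        got = score_special(t, _aln("K", "K"), _aln("E", "E", "B"), matrices)
        assert got == pytest.approx(matrices.ss_special.lookup("K", "E"))
        assert got != 0.0

    def test_mutated_salt_bridge_partner_scores_zero_cell(self):
        t = _single_pair_template("K", "E", special="salt_bridge")
        matrices, _ = derive_matrix_set([t])
        got = score_special(t, _aln("K", "K"), _aln("E", "L", "B"), matrices)
        assert got == matrices.ss_special.lookup("K", "L") == 0.0


class TestSimTerm:
    def test_self_alignment_scores_cp(self, toy_template, blosum):
        aln_a = _aln(toy_template.chain_a_seq, toy_template.chain_a_seq, "A")
        aln_b = _aln(toy_template.chain_b_seq, toy_template.chain_b_seq, "B")
        assert score_sim(toy_template, aln_a, aln_b, blosum) == \
            pytest.approx(toy_template.cp)

    def test_blosum_ratio_for_one_substitution(self, blosum):
        # contact pair (W, L), candidate (W, I):
        # (K_WW + K_LI) / (K_WW + K_LL) = (11 + 2) / (11 + 4)
        t = _single_pair_template("W", "L")
        got = score_sim(t, _aln("W", "W"), _aln("L", "I", "B"), blosum)
        assert got == pytest.approx(13.0 / 15.0)

    def test_both_positions_gapped_scores_zero(self, blosum):
        t = _single_pair_template("W", "L")
        got = score_sim(t, _aln("W", "W", gap_positions=(1,)),
                        _aln("L", "I", "B", gap_positions=(1,)), blosum)
        assert got == 0.0


class TestConsTerm:
    def test_self_alignment_reproduces_profile_arithmetic(self, blosum):
        t = _single_pair_template("W", "L")
        profile_a = build_profile(["W"])
        profile_b = build_profile(["L"], chain_id="B")
        got = score_cons(profile_a, profile_b, t, _aln("W", "W"),
                         _aln("L", "L", "B"), blosum)
        expected = (profile_a.score(1, "W") + profile_b.score(1, "L")) / \
            (blosum.K("W", "W") + blosum.K("L", "L"))
        assert got == pytest.approx(expected)

    def test_deviating_from_conserved_column_lowers_score(self, blosum):
        t = _single_pair_template("K", "L")
        profile_a = build_profile(["K"] * 1)
        profile_b = build_profile(["L"], chain_id="B")
        conserved = score_cons(profile_a, profile_b, t, _aln("K", "K"),
                               _aln("L", "L", "B"), blosum)
        mutated = score_cons(profile_a, profile_b, t, _aln("K", "D"),
                             _aln("L", "L", "B"), blosum)
        assert mutated < conserved

    def test_all_contacts_gapped_scores_zero(self, blosum):
        t = _single_pair_template("W", "L")
        got = score_cons(build_profile(["W"]), build_profile(["L"], chain_id="B"),
                         t, _aln("W", "W", gap_positions=(1,)),
                         _aln("L", "L", "B", gap_positions=(1,)), blosum)
        assert got == 0.0

    def test_profile_length_mismatch_is_an_error(self, blosum):
        t = _single_pair_template("W", "L")
        with pytest.raises(ValueError, match="length"):
            score_cons(build_profile(["WW"]), build_profile(["L"], chain_id="B"),
                       t, _aln("W", "W"), _aln("L", "L", "B"), blosum)


class TestTotalScore:
    def test_weighted_sum_arithmetic(self):
        assert total_score(1.0, 2.0, 3.0, 4.0, w=3.0).e_tot == 18.0

    def test_zero_weight_removes_cons_dependence(self):
        assert total_score(1.0, 2.0, 3.0, 100.0, w=0.0).e_tot == \
            total_score(1.0, 2.0, 3.0, -100.0, w=0.0).e_tot

    def test_additivity_in_sim_term(self):
        base = total_score(1.0, 2.0, 3.0, 4.0)
        shifted = total_score(1.0, 2.0, 3.0 + 0.7, 4.0)
        assert shifted.e_tot - base.e_tot == pytest.approx(0.7)

    def test_breakdown_identity_holds(self, toy_template, toy_matrices,
                                      toy_profiles):
        profile_a, profile_b = toy_profiles
        e = score_candidate(toy_template, self_alignment(profile_a),
                            self_alignment(profile_b), toy_matrices,
                            profile_a, profile_b, w=3.0)
        assert e.e_tot == pytest.approx(
            e.e_vdw + e.e_sf + e.e_sim + 3.0 * e.e_cons
        )


class TestNullModel:
    def test_reproducible_bit_exact_from_seed(self, toy_template, toy_matrices,
                                              toy_profiles, toy_background):
        profile_a, profile_b = toy_profiles
        kwargs = dict(n_samples=200, mutation_fraction=0.6, seed=123)
        nm1 = build_null_model(toy_template, toy_matrices, profile_a,
                               profile_b, toy_background, **kwargs)
        nm2 = build_null_model(toy_template, toy_matrices, profile_a,
                               profile_b, toy_background, **kwargs)
        assert nm1.mean == nm2.mean and nm1.sd == nm2.sd

    def test_zero_mutation_fraction_is_degenerate(self, toy_template,
                                                  toy_matrices, toy_profiles,
                                                  toy_background):
        profile_a, profile_b = toy_profiles
        with pytest.raises(DegenerateModelError):
            build_null_model(toy_template, toy_matrices, profile_a, profile_b,
                             toy_background, n_samples=50,
                             mutation_fraction=0.0, seed=1)

    def test_z_of_mean_and_three_sigma(self, toy_template, toy_matrices,
                                       toy_profiles, toy_background):
        profile_a, profile_b = toy_profiles
        nm = build_null_model(toy_template, toy_matrices, profile_a, profile_b,
                              toy_background, n_samples=200, seed=5)
        assert z_value(nm.mean, nm) == 0.0
        assert z_value(nm.mean + 3.0 * nm.sd, nm) == pytest.approx(3.0)
        # linearity
        assert z_value(10.0, nm) - z_value(4.0, nm) == \
            pytest.approx(6.0 / nm.sd)

    def test_native_interface_scores_above_null(self, toy_template,
                                                toy_matrices, toy_profiles,
                                                toy_background):
        profile_a, profile_b = toy_profiles
        nm = build_null_model(toy_template, toy_matrices, profile_a, profile_b,
                              toy_background, n_samples=300, seed=9)
        native = score_candidate(
            toy_template, self_alignment(profile_a), self_alignment(profile_b),
            toy_matrices, profile_a, profile_b,
        ).e_tot
        assert z_value(native, nm) > 0.0

    def test_null_samples_standardize_to_unit_normal(self, toy_template,
                                                     toy_matrices,
                                                     toy_profiles,
                                                     toy_background):
        """A fresh draw from the null, standardised by another fit of the
        null, has mean ~ 0 and sd ~ 1 (within 3/sqrt(n))."""
        profile_a, profile_b = toy_profiles
        n = 400
        nm1 = build_null_model(toy_template, toy_matrices, profile_a,
                               profile_b, toy_background, n_samples=n, seed=21)
        nm2 = build_null_model(toy_template, toy_matrices, profile_a,
                               profile_b, toy_background, n_samples=n, seed=22)
        z_mean = z_value(nm2.mean, nm1)
        tol = 3.0 / math.sqrt(n)
        assert abs(z_mean) < 3.0 * tol  # mean of n samples: sd/sqrt(n) scale
        assert abs(nm2.sd / nm1.sd - 1.0) < 4.0 * tol

    def test_two_residue_toy_matches_exhaustive_enumeration(self, blosum):
        """On a tiny alphabet the sampled null matches the exactly enumerated
        mutation distribution (all residues mutated, fraction 1.0)."""
        alphabet = "EKL"
        t = _single_pair_template("K", "E")
        scores = np.array([
            [0.0, -1.0, 0.5],   # E row vs E K L
            [-1.0, 0.0, 0.2],
            [0.5, 0.2, 1.0],
        ])
        zeros = np.zeros((3, 3))
        pm = lambda cls, s: PairScoringMatrix(cls=cls, scores=s,
                                              alphabet=alphabet)
        matrices = MatrixSet(
            ss_vdw=pm("ss_vdw", scores), sb_vdw=pm("sb_vdw", zeros),
            ss_special=pm("ss_special", zeros), sb_special=pm("sb_special", zeros),
            substitution=blosum,
        )
        background = np.array([0.5, 0.3, 0.2])
        profile_a = build_profile(["K"])
        profile_b = build_profile(["E"], chain_id="B")

        # exhaustive enumeration over both mutated positions
        outcomes = []
        for a_new, b_new in itertools.product("EL", "KL"):
            p_a = background[alphabet.index(a_new)] / (0.5 + 0.2)
            p_b = background[alphabet.index(b_new)] / (0.3 + 0.2)
            aln_a = _identity_alignment("A", "K", a_new)
            aln_b = _identity_alignment("B", "E", b_new)
            e = score_candidate(t, aln_a, aln_b, matrices, profile_a,
                                profile_b).e_tot
            outcomes.append((p_a * p_b, e))
        mean_exact = sum(p * e for p, e in outcomes)
        var_exact = sum(p * (e - mean_exact) ** 2 for p, e in outcomes)

        nm = build_null_model(t, matrices, profile_a, profile_b, background,
                              n_samples=4000, mutation_fraction=1.0, seed=77)
        assert nm.mean == pytest.approx(mean_exact, abs=0.05)
        assert nm.sd == pytest.approx(math.sqrt(var_exact), abs=0.05)


class TestResidueContribution:
    def test_alanine_to_alanine_is_zero(self, toy_matrices):
        t = _single_pair_template("A", "L")
        rec = residue_contribution(t, "A", 1, toy_matrices,
                                   build_profile(["A"]),
                                   build_profile(["L"], chain_id="B"))
        assert rec.contribution == pytest.approx(0.0)
        assert rec.wild_type == "A"

    def test_single_pair_arithmetic(self, toy_matrices, blosum):
        t = _single_pair_template("W", "L")
        profile_a = build_profile(["W"])
        profile_b = build_profile(["L"], chain_id="B")
        rec = residue_contribution(t, "A", 1, toy_matrices, profile_a,
                                   profile_b)
        d_vdw = toy_matrices.ss_vdw.lookup("W", "L") - \
            toy_matrices.ss_vdw.lookup("A", "L")
        denom = blosum.K("W", "W") + blosum.K("L", "L")
        d_sim = (blosum.K("W", "W") - blosum.K("W", "A")) / denom
        d_cons = (profile_a.score(1, "W") - profile_a.score(1, "A")) / denom
        assert rec.contribution == pytest.approx(d_vdw + d_sim + 3.0 * d_cons)

    def test_non_contact_position_is_an_error(self, toy_template,
                                              toy_matrices, toy_profiles):
        profile_a, profile_b = toy_profiles
        non_contact = max(toy_template.contact_residues_a) + 1
        with pytest.raises(ValueError, match="not a contact residue"):
            residue_contribution(toy_template, "A", non_contact, toy_matrices,
                                 profile_a, profile_b)

    def test_contact_residue_without_pairs_contributes_zero(self, toy_matrices):
        t = _single_pair_template("W", "L")
        t.contact_residues_a = (1, 2)
        t.chain_a_seq = "WK"
        profile_a = build_profile(["WK"])
        profile_b = build_profile(["L"], chain_id="B")
        rec = residue_contribution(t, "A", 2, toy_matrices, profile_a,
                                   profile_b)
        assert rec.contribution == pytest.approx(0.0)
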