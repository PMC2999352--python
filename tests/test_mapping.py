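"""Candidate enumeration, per-species ranking, acceptance and evaluation."""

from __future__ import annotations

import math

import pytest

from interolog3d import (
    ScoredCandidate,
    SequenceRecord,
    apply_acceptance,
    enumerate_candidates,
    evaluate_precision_recall,
    label_by_rss,
    parse_fasta_db,
    rank_within_species,
)
from interolog3d.mapping import sweep_thresholds
from interolog3d.scoring import EnergyBreakdown, NullModel, _identity_alignment
from interolog3d.synthetic import calcineurin_rss_table, calcineurin_search_rows


def _candidate(template="t", id_a="A1", id_b="B1", species="yeast", z=5.0,
               e_tot=50.0, rank=None):
    aln = _identity_alignment("A", "MKTW", "MKTW")
    return ScoredCandidate(
        template_id=template, id_a=id_a, id_b=id_b, species=species,
        aln_a=aln, aln_b=aln,
        energy=EnergyBreakdown(e_vdw=e_tot, e_sf=0, e_sim=0, e_cons=0),
        z=z, species_rank=rank,
    )


class TestEnumerateCandidates:
    def test_template_chains_only_give_the_self_pair(self, toy_template,
                                                     toy_matrices,
                                                     toy_profiles):
        profile_a, profile_b = toy_profiles
        db = [
            SequenceRecord("selfA", "human", toy_template.chain_a_seq),
            SequenceRecord("selfB", "human", toy_template.chain_b_seq),
        ]
        null = NullModel(template_id="toy", n_samples=100,
                         mutation_fraction=0.6, mean=20.0, sd=4.0, seed=0)
        cands = enumerate_candidates(toy_template, db, profile_a, profile_b,
                                     toy_matrices, null)
        assert len(cands) == 1
        c = cands[0]
        assert (c.id_a, c.id_b) == ("selfA", "selfB")
        assert c.aln_a.identity == c.aln_b.identity == 1.0
        assert c.aln_a.cr == c.aln_b.cr == 1.0

    def test_cross_product_bound_within_one_species(self, toy_template,
                                                    toy_matrices,
                                                    toy_profiles):
        profile_a, profile_b = toy_profiles
        db = [
            SequenceRecord(f"A{i}", "fly", toy_template.chain_a_seq)
            for i in range(3)
        ] + [
            SequenceRecord(f"B{i}", "fly", toy_template.chain_b_seq)
            for i in range(2)
        ]
        null = NullModel(template_id="toy", n_samples=100,
                         mutation_fraction=0.6, mean=20.0, sd=4.0, seed=0)
        cands = enumerate_candidates(toy_template, db, profile_a, profile_b,
                                     toy_matrices, null)
        assert len(cands) <= 6
        assert len(cands) == 6  # all identical copies pass the filter

    def test_same_species_pairing_only(self, toy_template, toy_matrices,
                                       toy_profiles):
        profile_a, profile_b = toy_profiles
        db = [
            SequenceRecord("a_fly", "fly", toy_template.chain_a_seq),
            SequenceRecord("b_yeast", "yeast", toy_template.chain_b_seq),
        ]
        null = NullModel(template_id="toy", n_samples=100,
                         mutation_fraction=0.6, mean=20.0, sd=4.0, seed=0)
        assert enumerate_candidates(toy_template, db, profile_a, profile_b,
                                    toy_matrices, null) == []

    def test_member_failing_cr_is_excluded(self, toy_template, toy_matrices,
                                           toy_profiles):
        """A family member whose alignment misses the interface fails CR."""
        profile_a, profile_b = toy_profiles
        # candidate = non-interface tail of chain A only (contacts 1..26)
        tail = toy_template.chain_a_seq[26:]
        db = [
            SequenceRecord("tailA", "fly", tail),
            SequenceRecord("selfB", "fly", toy_template.chain_b_seq),
        ]
        null = NullModel(template_id="toy", n_samples=100,
                         mutation_fraction=0.6, mean=20.0, sd=4.0, seed=0)
        cands = enumerate_candidates(toy_template, db, profile_a, profile_b,
                                     toy_matrices, null, evalue_max=1e6)
        assert all(c.id_a != "tailA" for c in cands)

    def test_empty_family_gives_empty_result(self, toy_template, toy_matrices,
                                             toy_profiles):
        profile_a, profile_b = toy_profiles
        db = [SequenceRecord("x", "fly", "PPPPGGGGSSPPPPGGGGSS")]
        null = NullModel(template_id="toy", n_samples=100,
                         mutation_fraction=0.6, mean=20.0, sd=4.0, seed=0)
        assert enumerate_candidates(toy_template, db, profile_a, profile_b,
                                    toy_matrices, null) == []


class TestRankWithinSpecies:
    def test_sorted_by_z_descending(self):
        cands = [
            _candidate(id_a="P48456", id_b="P48451", species="fly", z=8.98),
            _candidate(id_a="P48456", id_b="P47948", species="fly", z=4.42),
        ]
        ranked = rank_within_species(cands)
        by_pair = {(c.id_a, c.id_b): c.species_rank for c in ranked}
        assert by_pair[("P48456", "P48451")] == 1
        assert by_pair[("P48456", "P47948")] == 2

    def test_tied_z_broken_by_e_tot(self):
        cands = [
            _candidate(id_a="low", z=5.0, e_tot=10.0),
            _candidate(id_a="high", z=5.0, e_tot=20.0),
        ]
        ranked = rank_within_species(cands)
        assert {c.id_a: c.species_rank for c in ranked} == \
            {"high": 1, "low": 2}

    def test_single_candidate_ranks_first(self):
        assert rank_within_species([_candidate()])[0].species_rank == 1

    def test_ranks_are_a_permutation_per_partition(self):
        cands = [
            _candidate(id_a=f"A{i}", species=s, z=float(i % 5))
            for i in range(20) for s in ("fly", "yeast")
        ]
        ranked = rank_within_species(cands)
        for species in ("fly", "yeast"):
            ranks = sorted(c.species_rank for c in ranked
                           if c.species == species)
            assert ranks == list(range(1, 21))

    def test_species_partitions_are_independent(self):
        cands = [
            _candidate(id_a="f", species="fly", z=1.0),
            _candidate(id_a="y", species="yeast", z=9.0),
        ]
        ranked = rank_within_species(cands)
        assert all(c.species_rank == 1 for c in ranked)


class TestApplyAcceptance:
    @pytest.mark.parametrize(
        "z,rank,expected",
        [
            (8.98, 1, True),    # top fruit-fly hit: accepted
            (3.03, 50, False),  # above Z floor but ranked 50: rejected
            (2.86, 6, False),   # good rank but Z below 3: rejected
            (3.0, 25, True),    # boundary: Z >= 3 and rank <= 25
        ],
    )
    def test_z_and_rank_cascade(self, z, rank, expected):
        accepted = apply_acceptance([_candidate(z=z, rank=rank)])
        assert (len(accepted) == 1) is expected

    def test_unranked_candidates_are_an_error(self):
        with pytest.raises(ValueError, match="ranked"):
            apply_acceptance([_candidate(rank=None)])

    def test_acceptance_sets_are_nested(self):
        cands = [
            _candidate(id_a=f"A{i}", z=z, rank=r)
            for i, (z, r) in enumerate(
                [(8.0, 1), (5.0, 3), (3.5, 10), (3.1, 30), (2.0, 2)]
            )
        ]
        loose = {(c.id_a, c.id_b)
                 for c in apply_acceptance(cands, z_min=3.0, rank_max=25)}
        tight = {(c.id_a, c.id_b)
                 for c in apply_acceptance(cands, z_min=4.0, rank_max=5)}
        assert tight <= loose


class TestRssLabels:
    def test_worked_example_negatives_match_printed_set(self):
        rows = calcineurin_search_rows()
        annotations = label_by_rss(
            [(r.interactor1, r.interactor2) for r in rows],
            calcineurin_rss_table(),
            positives={(r.interactor1, r.interactor2)
                       for r in rows if r.label == "P"},
        )
        negatives = {(a.id_a, a.id_b) for a in annotations
                     if a.label == "negative"}
        printed = {(r.interactor1, r.interactor2)
                   for r in rows if r.label == "N"}
        assert negatives == printed
        assert len(negatives) == 9

    def test_cc_above_threshold_is_not_negative(self):
        annotations = label_by_rss(
            [("P48456", "P49258")], {("P48456", "P49258"): (0.41, 0.56)},
            positives={("P48456", "P49258")},
        )
        assert annotations[0].label == "positive"

    def test_missing_scores_are_unknown(self):
        annotations = label_by_rss([("x", "y")], {})
        assert annotations[0].label == "unknown"
        assert annotations[0].cc_rss is None


class TestEvaluation:
    def _labels(self):
        return label_by_rss(
            [("a", "1"), ("b", "2"), ("c", "3"), ("d", "4"), ("e", "5")],
            {("e", "5"): (0.2, 0.2)},
            positives={("a", "1"), ("b", "2"), ("c", "3"), ("d", "4")},
        )

    def test_precision_and_recall_arithmetic(self):
        ev = evaluate_precision_recall([("a", "1"), ("b", "2")], self._labels())
        assert ev.precision == 1.0
        assert ev.recall == 0.5

    def test_unknown_hits_excluded_from_precision(self):
        labels = self._labels() + label_by_rss([("u", "9")], {})
        ev = evaluate_precision_recall([("a", "1"), ("u", "9"), ("e", "5")],
                                       labels)
        assert ev.precision == 0.5  # 1 positive / (1 positive + 1 negative)

    def test_no_hits_gives_nan_precision_zero_recall(self):
        ev = evaluate_precision_recall([], self._labels())
        assert math.isnan(ev.precision)
        assert ev.recall == 0.0

    def test_zero_positives_is_an_error(self):
        labels = label_by_rss([("e", "5")], {("e", "5"): (0.2, 0.2)})
        with pytest.raises(ValueError, match="recall undefined"):
            evaluate_precision_recall([], labels)

    def test_recall_non_increasing_over_z_sweep(self):
        cands = [
            _candidate(id_a=c, id_b=str(i), z=z, rank=1)
            for i, (c, z) in enumerate(
                zip("abcde", [8.0, 5.0, 3.5, 3.1, 2.0])
            )
        ]
        cands = rank_within_species(cands)
        rows = sweep_thresholds(cands, self._labels(),
                                z_grid=[2.0, 3.0, 4.0, 6.0, 9.0])
        recalls = [r["recall"] for r in rows]
        assert recalls == sorted(recalls, reverse=True)


class TestFastaDb:
    def test_header_species_parsing(self):
        text = ">P1|yeast some description\nMKTW\n>bad header\nAAAA\n"
        records = parse_fasta_db(text)
        assert len(records) == 1
        assert records[0] == SequenceRecord("P1", "yeast", "MKTW")

    def test_custom_header_regex(self):
        text = ">sp_P1_human\nMKTW\n"
        records = parse_fasta_db(
            text, header_regex=r"^sp_(?P<id>\w+?)_(?P<species>\w+)$"
        )
        assert records[0].id == "P1"
        assert records[0].species == "human"
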