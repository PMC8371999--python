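"""Micro/macro/F/MRR/NumCon evaluation framework."""

import numpy as np
import pytest

from layglove.evaluate import (MatchRecord, compare_algorithms, evaluate,
                               macro_metrics, mean_reciprocal_rank, micro_metrics,
                               paired_hit_test, score_lists, sweep_candidate_size)
from layglove.glove import EmbeddingModel
from layglove.groundtruth import SeedAssignment
from layglove.ranking import CandidateList


def make_list(seed, tokens, n=None):
    n = n if n is not None else len(tokens)
    scores = [1.0 - 0.01 * i for i in range(len(tokens))]
    return CandidateList(seed, tuple(zip(tokens, scores)), n)


def worked_scenario():
    """25 concepts x 4 synonyms; 20 generated lists of 5 candidates; 15
    lists contain exactly 2 true synonyms each (30 true positives)."""
    assignments, lists = [], {}
    for k in range(25):
        cui = f"C{k:03d}"
        syns = [f"c{k}syn{i}" for i in range(4)]
        assignments.append(SeedAssignment(cui, syns[0], frozenset(syns[1:])))
        if k < 20:
            if k < 15:
                tokens = [syns[1], "junk1", "junk2", syns[2], "junk3"]
            else:
                tokens = ["junk1", "junk2", "junk3", "junk4", "junk5"]
            lists[cui] = make_list(syns[0], tokens)
        else:
            lists[cui] = None
    return lists, assignments


class TestWorkedScenario:
    def test_all_four_printed_ratios_reproduce_exactly(self):
        lists, assignments = worked_scenario()
        records = score_lists(lists, assignments)
        micro = micro_metrics(records, assignments, n=5)
        macro = macro_metrics(records, dataset_size=25)
        assert micro.precision == 30 / 100 == 0.30
        assert micro.recall == 30 / 75 == 0.40
        assert macro.precision == 15 / 20 == 0.75
        assert macro.recall == 15 / 25 == 0.60

    def test_full_report_bookkeeping(self):
        lists, assignments = worked_scenario()
        report = evaluate(lists, assignments, n=5, dataset_size=25)
        assert report.num_con == 15
        assert report.lists_generated == 20
        assert report.total_truths == 75
        assert report.true_positive_count == 30


class TestScoreLists:
    A = [SeedAssignment("C1", "s", frozenset({"t1", "t2"}))]

    def test_both_held_out_synonyms_found(self):
        recs = score_lists({"C1": make_list("s", ["t1", "x", "t2"])}, self.A)
        assert recs[0].n_true == 2

    def test_no_overlap(self):
        recs = score_lists({"C1": make_list("s", ["x", "y"])}, self.A)
        assert recs[0].n_true == 0 and recs[0].generated

    def test_duplicate_candidate_counts_once(self):
        recs = score_lists({"C1": make_list("s", ["t1", "t1", "t1"])}, self.A)
        assert recs[0].n_true == 1
        assert recs[0].hit_ranks == (1,)

    def test_missing_assignment_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            score_lists({}, self.A)


class TestMetricEdges:
    def test_no_lists_generated_reports_zero(self):
        a = [SeedAssignment("C1", "s", frozenset({"t"}))]
        records = score_lists({"C1": None}, a)
        micro = micro_metrics(records, a, n=5)
        assert (micro.precision, micro.recall, micro.f_score) == (0.0, 0.0, 0.0)

    def test_perfect_recall_when_lists_hold_all_truths(self):
        a = [SeedAssignment("C1", "s", frozenset({"t1", "t2"}))]
        records = score_lists({"C1": make_list("s", ["t1", "t2"])}, a)
        assert micro_metrics(records, a, n=2).recall == 1.0

    def test_macro_hand_count(self):
        records = [
            MatchRecord("C1", True, (2,), 5),
            MatchRecord("C2", True, (), 5),
        ]
        m = macro_metrics(records, dataset_size=4)
        assert (m.precision, m.recall) == (0.5, 0.25)

    def test_f_is_harmonic_mean_and_bounded(self):
        m = macro_metrics([MatchRecord("C1", True, (1,), 5)], dataset_size=2)
        p, r = m.precision, m.recall
        assert m.f_score == pytest.approx(2 * p * r / (p + r))
        assert 0.0 <= m.f_score <= 1.0


class TestMRR:
    def test_first_candidate_hit_scores_one(self):
        assert mean_reciprocal_rank([MatchRecord("C1", True, (1,), 5)]) == 1.0

    def test_hand_arithmetic_over_two_lists(self):
        recs = [MatchRecord("C1", True, (2,), 5), MatchRecord("C2", True, (4,), 5)]
        assert mean_reciprocal_rank(recs) == pytest.approx((0.5 + 0.25) / 2)

    def test_no_hits_anywhere(self):
        assert mean_reciprocal_rank([MatchRecord("C1", True, (), 5)]) == 0.0

    def test_hits_only_averaging_mode(self):
        recs = [MatchRecord("C1", True, (2,), 5), MatchRecord("C2", True, (), 5)]
        assert mean_reciprocal_rank(recs, over="generated") == pytest.approx(0.25)
        assert mean_reciprocal_rank(recs, over="hits") == pytest.approx(0.5)


class TestSweep:
    def hand_model(self):
        # only truth vector sits at rank 3 for the seed
        vecs = {
            "seed": (1.0, 0.0),
            "d1": (0.99, 0.14),
            "d2": (0.97, 0.24),
            "truth": (0.9, 0.44),
            "far1": (0.0, 1.0),
            "far2": (-1.0, 0.0),
        }
        tokens = list(vecs)
        return EmbeddingModel(tokens=tokens,
                              vectors=np.array([vecs[t] for t in tokens]))

    def test_numcon_jumps_at_the_truth_rank(self):
        model = self.hand_model()
        a = [SeedAssignment("C1", "seed", frozenset({"truth"}))]
        table = sweep_candidate_size(model, a, n_values=[1, 2, 3, 4])
        assert list(table["num_con"]) == [0, 0, 1, 1]

    def test_recall_and_numcon_are_non_decreasing_in_n(self):
        model = self.hand_model()
        a = [SeedAssignment("C1", "seed", frozenset({"truth", "far1"}))]
        table = sweep_candidate_size(model, a, n_values=list(range(1, 6)))
        assert (table["micro_recall"].diff().dropna() >= 0).all()
        assert (table["num_con"].diff().dropna() >= 0).all()

    def test_invalid_n_values_rejected(self):
        with pytest.raises(ValueError):
            sweep_candidate_size(self.hand_model(), [], n_values=[3, 1])


class TestCompareAlgorithms:
    def test_printed_averaged_macro_f_gives_25_percent(self):
        assert compare_algorithms(48.835, 61.08) == 25

    def test_averaging_two_datasets_first(self):
        assert compare_algorithms([48.44, 49.23], [57.87, 64.29]) == 25

    def test_equal_reports_and_decline(self):
        assert compare_algorithms(50.0, 50.0) == 0
        assert compare_algorithms(50.0, 40.0) == -20

    def test_zero_baseline_is_undefined(self):
        assert compare_algorithms(0.0, 10.0) is None


class TestPairedHitTest:
    def test_no_discordance_gives_p_one(self):
        assert paired_hit_test([True, False], [True, False]) == 1.0

    def test_symmetric_and_bounded(self):
        a = [True] * 10 + [False] * 10
        b = [False] * 6 + [True] * 14
        p = paired_hit_test(a, b)
        assert p == paired_hit_test(b, a)
        assert 0.0 < p <= 1.0

    def test_strong_one_sided_discordance_is_significant(self):
        a = [False] * 20
        b = [True] * 20
        assert paired_hit_test(a, b) < 0.001
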