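"""Ranked split of relational synsets and corpus rewriting."""

import random

import pytest

from layglove.expansion import ExpansionPlan, expand_corpus, rank_and_split
from layglove.glove import build_cooccurrence
from layglove.lexicon import RelatedTerm, RelationKind
from layglove.textprep import TokenizedCorpus

SYN = RelationKind.SYNONYM


def scored(pairs):
    return [RelatedTerm(s, SYN, score=v) for s, v in pairs]


class TestRankAndSplit:
    def test_halves_split_reproduces_contiguous_example(self):
        items = scored([("worry", 4.0), ("cephalalgia", 3.5),
                        ("concern", 3.0), ("vexation", 2.5)])
        assert rank_and_split(items, mode="halves") == (
            ["worry", "cephalalgia"], ["concern", "vexation"]
        )

    def test_roundrobin_alternates_and_balances_similarity(self):
        items = scored([("a", 5), ("b", 4), ("c", 3), ("d", 2), ("e", 1)])
        left, right = rank_and_split(items, mode="roundrobin")
        assert (left, right) == (["a", "c", "e"], ["b", "d"])
        # totals 9 vs 6: closer than any contiguous split of this list

    def test_empty_input(self):
        assert rank_and_split([]) == ([], [])

    def test_cap_limits_to_ten_most_similar(self):
        items = scored([(f"x{i:02d}", 12 - i) for i in range(12)])
        left, right = rank_and_split(items, cap=10)
        assert len(left) + len(right) == 10
        assert "x10" not in left + right and "x11" not in left + right

    def test_ties_break_lexicographically(self):
        items = scored([("b", 1.0), ("a", 1.0), ("c", 2.0)])
        left, right = rank_and_split(items, mode="halves")
        assert left + right == ["c", "a", "b"]

    def test_negative_cap_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            rank_and_split([], cap=-1)


def make_plan(seed, left, right):
    return ExpansionPlan(seed, SYN, tuple(left), tuple(right))


class TestExpandCorpus:
    def test_insertions_straddle_each_seed_occurrence(self):
        corpus = TokenizedCorpus([["i", "had", "a", "headache"]])
        plan = make_plan("headache", ["worry", "cephalalgia"], ["concern", "vexation"])
        out = expand_corpus(corpus, {"headache": plan})
        assert out.documents == [
            ["i", "had", "a", "worry", "cephalalgia", "headache", "concern", "vexation"]
        ]

    def test_corpus_without_seed_occurrences_is_unchanged(self):
        corpus = TokenizedCorpus([["no", "seeds", "here"]])
        out = expand_corpus(corpus, {"headache": make_plan("headache", ["x"], ["y"])})
        assert out.documents == corpus.documents
        assert not out.expansion_log

    def test_token_count_grows_by_occurrences_times_insertions(self):
        corpus = TokenizedCorpus([["s", "a", "s"], ["b"]])
        plan = make_plan("s", ["x1", "x2"], ["y1", "y2"])
        out = expand_corpus(corpus, {"s": plan})
        assert out.corpus.n_tokens == corpus.n_tokens + 2 * 4
        assert out.expansion_log["s"] == 2

    def test_inserted_tokens_are_never_themselves_expanded(self):
        # "a" inserts "b"; "b" inserts "c": inserted b must stay bare
        corpus = TokenizedCorpus([["a", "b"]])
        plans = {"a": make_plan("a", ["b"], []), "b": make_plan("b", ["c"], [])}
        out = expand_corpus(corpus, plans)
        assert out.documents == [["b", "a", "c", "b"]]

    def test_count_conservation_on_random_corpora(self):
        rng = random.Random(11)
        for _ in range(20):
            docs = [
                [rng.choice("abcdefg") for _ in range(rng.randint(0, 30))]
                for _ in range(rng.randint(1, 8))
            ]
            corpus = TokenizedCorpus(docs)
            plans = {
                "a": make_plan("a", ["ins1"], ["ins2", "ins3"]),
                "d": make_plan("d", [], ["ins4"]),
            }
            out = expand_corpus(corpus, plans)
            expected = corpus.n_tokens + sum(
                sum(doc.count(s) for doc in docs) * (len(p.left) + len(p.right))
                for s, p in plans.items()
            )
            assert out.corpus.n_tokens == expected

    def test_deleting_inserted_tokens_recovers_original_order(self):
        rng = random.Random(7)
        docs = [[rng.choice("abcde") for _ in range(25)] for _ in range(5)]
        corpus = TokenizedCorpus(docs)
        plans = {"b": make_plan("b", ["u", "v"], ["w"])}
        out = expand_corpus(corpus, plans)
        inserted = {"u", "v", "w"}
        recovered = [[t for t in doc if t not in inserted] for doc in out.documents]
        assert recovered == docs


class TestCooccurrenceIdealisation:
    """With flat weighting and a window covering the whole insertion, the
    seed's co-occurrence row gains exactly occurrences(s) per inserted
    token: the expanded row equals the original plus the insertion
    contribution on inserted-token coordinates."""

    def test_expanded_row_equals_original_plus_insertions(self):
        docs = [
            ["w1", "w2", "s", "w3", "w4"],
            ["w5", "s", "w6"],
            ["w7", "w8", "w9"],
        ]
        corpus = TokenizedCorpus(docs)
        plan = make_plan("s", ["x1"], ["x2", "x3"])
        out = expand_corpus(corpus, {"s": plan})
        window = len(plan.left) + len(plan.right) + 1
        before = build_cooccurrence(docs, window=window, weighting="flat")
        after = build_cooccurrence(out.documents, window=window, weighting="flat")
        occurrences = 2
        for x in ("x1", "x2", "x3"):
            assert before.weight("s", x) == 0.0
            assert after.weight("s", x) == occurrences

    def test_pair_count_lower_bound_with_colliding_insertions(self):
        # inserted token also present elsewhere in the corpus: the pair
        # count must still be at least occurrences(s), though insertion may
        # shift pre-existing copies out of the window
        docs = [["x1", "q", "s", "q", "s"]]
        corpus = TokenizedCorpus(docs)
        plan = make_plan("s", ["x1"], [])
        out = expand_corpus(corpus, {"s": plan})
        occurrences = 2
        after = build_cooccurrence(out.documents, window=2, weighting="flat")
        assert after.weight("s", "x1") >= occurrences
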