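"""Co-occurrence counting and log-bilinear trainer behaviour."""

import io
import math
import random

import numpy as np
import pytest

from conftest import brute_force_cooccurrence, random_token_docs
from layglove.glove import (EmbeddingFormatError, TrainingConfig,
                            build_cooccurrence, load_embeddings,
                            save_embeddings, train_embeddings)


class TestBuildCooccurrence:
    def test_window_one_flat_counts_adjacent_pairs_only(self):
        m = build_cooccurrence([["a", "b", "c"]], window=1, weighting="flat")
        assert m.weight("a", "b") == 1.0
        assert m.weight("b", "c") == 1.0
        assert m.weight("a", "c") == 0.0

    def test_single_token_document_gives_empty_matrix(self):
        m = build_cooccurrence([["a"]], window=5)
        assert m.entries == {}

    def test_inverse_distance_discounts_by_separation(self):
        m = build_cooccurrence([["a", "b", "c"]], window=2, weighting="inverse-distance")
        assert m.weight("a", "c") == 0.5

    def test_windows_do_not_cross_document_boundaries(self):
        m = build_cooccurrence([["a"], ["b"]], window=5, weighting="flat")
        assert m.weight("a", "b") == 0.0

    def test_symmetry_and_bad_window(self):
        m = build_cooccurrence([["a", "b"]], window=1)
        assert m.weight("a", "b") == m.weight("b", "a")
        with pytest.raises(ValueError):
            build_cooccurrence([["a", "b"]], window=0)

    def test_matches_brute_force_enumeration_on_random_corpora(self):
        rng = random.Random(3)
        for _ in range(15):
            docs = random_token_docs(rng, rng.randint(1, 6), 60, 12)
            window = rng.randint(1, 8)
            for weighting in ("flat", "inverse-distance"):
                m = build_cooccurrence(docs, window=window, weighting=weighting)
                oracle = brute_force_cooccurrence(docs, window, weighting)
                got = {
                    tuple(sorted((m.tokens[i], m.tokens[j]))): w
                    for (i, j), w in m.entries.items()
                }
                assert got.keys() == oracle.keys()
                for k in oracle:
                    assert got[k] == pytest.approx(oracle[k], rel=1e-12)


class TestTrainer:
    def test_empty_matrix_returns_initialised_model_with_zero_loss(self):
        m = build_cooccurrence([["a"]], window=2)
        model = train_embeddings(m, TrainingConfig(dim=4, epochs=3, rng_seed=1))
        assert model.epoch_losses == [0.0, 0.0, 0.0]

    def test_two_token_corpus_converges_to_log_count(self):
        m = build_cooccurrence([["a", "b"]] * 50, window=1, weighting="flat")
        model = train_embeddings(m, TrainingConfig(dim=8, epochs=400, rng_seed=3))
        i, j = model.index["a"], model.index["b"]
        pred = model.W[i] @ model.W_ctx[j] + model.b[i] + model.b_ctx[j]
        assert abs(pred - math.log(50)) < 0.1

    def test_same_seed_is_bitwise_reproducible(self):
        docs = random_token_docs(random.Random(5), 8, 30, 10)
        m = build_cooccurrence(docs, window=4)
        cfg = TrainingConfig(dim=12, epochs=10, rng_seed=21)
        one = train_embeddings(m, cfg)
        two = train_embeddings(m, cfg)
        assert np.array_equal(one.vectors, two.vectors)
        assert one.epoch_losses == two.epoch_losses

    def test_different_seeds_differ(self):
        m = build_cooccurrence([["a", "b", "c", "a"]], window=2)
        one = train_embeddings(m, TrainingConfig(dim=4, epochs=2, rng_seed=1))
        two = train_embeddings(m, TrainingConfig(dim=4, epochs=2, rng_seed=2))
        assert not np.array_equal(one.vectors, two.vectors)

    def test_mean_epoch_loss_is_non_increasing(self):
        docs = random_token_docs(random.Random(9), 20, 40, 15)
        m = build_cooccurrence(docs, window=5)
        model = train_embeddings(m, TrainingConfig(dim=16, epochs=30, rng_seed=7))
        for prev, cur in zip(model.epoch_losses, model.epoch_losses[1:]):
            assert cur <= prev * 1.02 + 1e-12  # slack for stochastic jitter

    def test_export_combines_main_and_context_vectors(self):
        m = build_cooccurrence([["a", "b"]] * 5, window=1)
        model = train_embeddings(m, TrainingConfig(dim=4, epochs=2, rng_seed=1))
        assert np.allclose(model.vectors, model.W + model.W_ctx)
        w_only = train_embeddings(m, TrainingConfig(dim=4, epochs=2, rng_seed=1,
                                                    combine="w"))
        assert np.allclose(w_only.vectors, w_only.W)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(dim=0)
        with pytest.raises(ValueError):
            TrainingConfig(alpha=0.0)


class TestEmbeddingIO:
    def test_save_load_round_trip(self):
        m = build_cooccurrence([["a", "b", "c", "a", "b"]], window=2)
        model = train_embeddings(m, TrainingConfig(dim=6, epochs=5, rng_seed=2))
        buf = io.StringIO()
        save_embeddings(model, buf)
        buf.seek(0)
        loaded = load_embeddings(buf)
        assert loaded.tokens == model.tokens
        assert np.allclose(loaded.vectors, model.vectors, atol=1e-6)

    def test_empty_model_round_trips_to_empty_file(self):
        buf = io.StringIO()
        save_embeddings(load_embeddings(io.StringIO("")), buf)
        assert buf.getvalue() == ""

    def test_ragged_rows_are_a_format_error(self):
        with pytest.raises(EmbeddingFormatError):
            load_embeddings(io.StringIO("a 1.0 2.0\nb 1.0\n"))
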