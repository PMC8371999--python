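"""Shared fixtures: the seeded synthetic benchmark and its pipeline runs.

The benchmark pipeline (preprocess -> ground truth -> [expand] -> co-occur
-> train -> rank -> evaluate) is expensive relative to unit tests, so it
runs once per session and its pieces are shared.
"""

from __future__ import annotations

import io
import random
from collections import defaultdict

import pytest

from layglove.evaluate import evaluate, generate_lists
from layglove.expansion import build_plans, expand_corpus
from layglove.glove import TrainingConfig, build_cooccurrence, train_embeddings
from layglove.groundtruth import assign_seeds, build_ground_truth, load_concept_mappings
from layglove.lexicon import RelationKind
from layglove.synthgen import SynthConfig, generate_benchmark
from layglove.textprep import preprocess_corpus, term_frequencies

# Benchmark-scale hyperparameters: a small window and vector size are
# enough for the planted structure, and keep the session fast.
BENCH_WINDOW = 10
BENCH_DIM = 50
BENCH_EPOCHS = 25
BENCH_SEED = 13
BENCH_N = 10


def brute_force_cooccurrence(documents, window, weighting):
    """Independent pair enumerator used as the co-occurrence oracle."""
    pairs = defaultdict(float)
    for doc in documents:
        n = len(doc)
        for p in range(n):
            for q in range(p + 1, min(p + window, n - 1) + 1):
                w = 1.0 if weighting == "flat" else 1.0 / (q - p)
                key = tuple(sorted((doc[p], doc[q])))
                pairs[key] += w
    return dict(pairs)


def random_token_docs(rng: random.Random, n_docs, max_len, vocab_size):
    vocab = [f"t{i}" for i in range(vocab_size)]
    return [
        [rng.choice(vocab) for _ in range(rng.randint(1, max_len))]
        for _ in range(n_docs)
    ]


@pytest.fixture(scope="session")
def bench():
    return generate_benchmark(SynthConfig(rng_seed=BENCH_SEED))


@pytest.fixture(scope="session")
def bench_pipeline(bench):
    """Both pipeline variants (basic and synonym-expanded) on the benchmark."""
    corpus = preprocess_corpus(bench.documents)
    records = load_concept_mappings(io.StringIO(bench.concept_tsv))
    dataset = build_ground_truth(records, term_frequencies(corpus))
    assignments = assign_seeds(dataset, rng_seed=BENCH_SEED)
    cfg = TrainingConfig(dim=BENCH_DIM, epochs=BENCH_EPOCHS, rng_seed=BENCH_SEED)

    basic_matrix = build_cooccurrence(corpus.documents, window=BENCH_WINDOW)
    basic_model = train_embeddings(basic_matrix, cfg)
    basic_report = evaluate(
        generate_lists(basic_model, assignments, n=BENCH_N),
        assignments, n=BENCH_N, dataset_size=len(dataset),
    )

    plans = build_plans(
        [a.seed_term for a in assignments], RelationKind.SYNONYM, bench.lexicon
    )
    expanded = expand_corpus(corpus, plans)
    syno_matrix = build_cooccurrence(expanded.documents, window=BENCH_WINDOW)
    syno_model = train_embeddings(syno_matrix, cfg)
    syno_report = evaluate(
        generate_lists(syno_model, assignments, n=BENCH_N),
        assignments, n=BENCH_N, dataset_size=len(dataset),
    )

    return {
        "corpus": corpus,
        "dataset": dataset,
        "assignments": assignments,
        "basic_model": basic_model,
        "basic_report": basic_report,
        "syno_model": syno_model,
        "syno_report": syno_report,
    }
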