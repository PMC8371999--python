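"""Synonym-retrieval evaluation: micro/macro precision-recall, MRR, NumCon.

Two averaging views are reported.  The *micro* view counts retrieved
synonym terms:

    P_micro = true synonyms in the candidate lists / (lists generated * n)
    R_micro = true synonyms in the candidate lists / total held-out synonyms

The *macro* view counts concepts with at least one retrieved synonym:

    P_macro = hit concepts / lists generated
    R_macro = hit concepts / concepts in the ground-truth dataset

F is the harmonic mean 2PR/(P+R), defined as 0 when P + R = 0.  NumCon is
the number of hit concepts, and MRR averages the reciprocal rank of the
first true synonym over generated lists (misses contribute 0 by default;
``over="hits"`` averages over hit lists only).

A candidate counts as a true synonym iff its stemmed surface equals one of
its concept's held-out synonyms, and each (concept, synonym) pair counts
at most once however often it recurs in the list.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .glove import EmbeddingModel
from .groundtruth import SeedAssignment
from .ranking import CandidateList, top_candidates

__all__ = [
    "Metrics",
    "MatchRecord",
    "EvaluationReport",
    "generate_lists",
    "score_lists",
    "micro_metrics",
    "macro_metrics",
    "mean_reciprocal_rank",
    "evaluate",
    "sweep_candidate_size",
    "compare_algorithms",
    "paired_hit_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_score: float


@dataclass(frozen=True)
class MatchRecord:
    """Per-concept match outcome: which held-out synonyms were found where."""

    cui: str
    generated: bool
    hit_ranks: tuple[int, ...]  # 1-based first rank of each matched synonym
    n_candidates: int

    @property
    def n_true(self) -> int:
        return len(self.hit_ranks)

    @property
    def first_hit_rank(self) -> int | None:
        return min(self.hit_ranks) if self.hit_ranks else None


@dataclass(frozen=True)
class EvaluationReport:
    num_con: int
    micro: Metrics
    macro: Metrics
    mrr: float
    lists_generated: int
    total_candidates: int
    total_truths: int
    true_positive_count: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _f_score(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def generate_lists(
    model: EmbeddingModel,
    assignments: Iterable[SeedAssignment],
    n: int = 10,
) -> dict[str, CandidateList | None]:
    """One candidate list per concept (``None`` when the seed is OOV)."""
    return {a.cui: top_candidates(model, a.seed_term, n=n) for a in assignments}


def score_lists(
    lists: Mapping[str, CandidateList | None],
    assignments: Iterable[SeedAssignment],
) -> list[MatchRecord]:
    """Match each concept's candidate list against its held-out synonyms."""
    by_cui = {a.cui: a for a in assignments}
    records = []
    for cui in sorted(by_cui):
        a = by_cui[cui]
        if cui not in lists:
            raise ValueError(f"no candidate list entry for concept {cui}")
        cl = lists[cui]
        if cl is None:
            records.append(MatchRecord(cui, False, (), 0))
            continue
        first_rank: dict[str, int] = {}
        for rank, (tok, _score) in enumerate(cl.candidates, start=1):
            if tok in a.held_out and tok not in first_rank:
                first_rank[tok] = rank
        records.append(
            MatchRecord(cui, True, tuple(sorted(first_rank.values())),
                        len(cl.candidates))
        )
    return records


def micro_metrics(
    records: Sequence[MatchRecord],
    assignments: Iterable[SeedAssignment],
    n: int,
) -> Metrics:
    """Term-level precision/recall/F over all candidate lists."""
    tp = sum(r.n_true for r in records)
    generated = sum(1 for r in records if r.generated)
    total_truths = sum(len(a.held_out) for a in assignments)
    if generated * n == 0 or total_truths == 0:
        logger.warning("micro metrics: zero denominator, reporting 0")
    p = tp / (generated * n) if generated * n else 0.0
    r = tp / total_truths if total_truths else 0.0
    return Metrics(p, r, _f_score(p, r))


def macro_metrics(records: Sequence[MatchRecord], dataset_size: int) -> Metrics:
    """Concept-level precision/recall/F.

    Precision divides by the number of *generated* lists (a concept whose
    seed was out of vocabulary is not charged against precision); recall
    divides by the full ground-truth dataset size.
    """
    hits = sum(1 for r in records if r.n_true > 0)
    generated = sum(1 for r in records if r.generated)
    if generated == 0 or dataset_size == 0:
        logger.warning("macro metrics: zero denominator, reporting 0")
    p = hits / generated if generated else 0.0
    r = hits / dataset_size if dataset_size else 0.0
    return Metrics(p, r, _f_score(p, r))


def mean_reciprocal_rank(records: Sequence[MatchRecord], over: str = "generated") -> float:
    """Mean of 1/(rank of first true synonym).

    ``over="generated"`` (default) averages over all generated lists with
    0 for lists without a hit; ``over="hits"`` averages over hit lists only.
    """
    if over not in ("generated", "hits"):
        raise ValueError("over must be 'generated' or 'hits'")
    if over == "generated":
        pool = [r for r in records if r.generated]
    else:
        pool = [r for r in records if r.n_true > 0]
    if not pool:
        return 0.0
    return sum(
        (1.0 / r.first_hit_rank) if r.first_hit_rank else 0.0 for r in pool
    ) / len(pool)


def evaluate(
    lists: Mapping[str, CandidateList | None],
    assignments: Sequence[SeedAssignment],
    n: int,
    dataset_size: int | None = None,
) -> EvaluationReport:
    """Full report over a set of candidate lists.

    ``dataset_size`` defaults to the number of assignments (the usual case
    where every ground-truth concept was queried).
    """
    assignments = list(assignments)
    if dataset_size is None:
        dataset_size = len(assignments)
    records = score_lists(lists, assignments)
    micro = micro_metrics(records, assignments, n)
    macro = macro_metrics(records, dataset_size)
    generated = [r for r in records if r.generated]
    return EvaluationReport(
        num_con=sum(1 for r in records if r.n_true > 0),
        micro=micro,
        macro=macro,
        mrr=mean_reciprocal_rank(records),
        lists_generated=len(generated),
        total_candidates=sum(r.n_candidates for r in generated),
        total_truths=sum(len(a.held_out) for a in assignments),
        true_positive_count=sum(r.n_true for r in records),
    )


def sweep_candidate_size(
    model: EmbeddingModel,
    assignments: Sequence[SeedAssignment],
    n_values: Sequence[int],
    dataset_size: int | None = None,
) -> pd.DataFrame:
    """Micro metrics and NumCon as the candidate-list size n varies.

    A single ranked scan at max(n) is reused: the list at any smaller n is
    a prefix of the list at a larger n, so hit ranks need computing once.
    Returns a table with columns n, num_con, micro precision/recall/f.
    """
    n_values = list(n_values)
    if not n_values or any(v <= 0 for v in n_values) or sorted(n_values) != n_values:
        raise ValueError("n_values must be positive and ascending")
    assignments = list(assignments)
    if dataset_size is None:
        dataset_size = len(assignments)
    full = generate_lists(model, assignments, n=max(n_values))
    records = score_lists(full, assignments)
    generated = sum(1 for r in records if r.generated)
    total_truths = sum(len(a.held_out) for a in assignments)
    rows = []
    for n in n_values:
        tp = sum(sum(1 for rank in r.hit_ranks if rank <= n) for r in records)
        hits = sum(1 for r in records if r.first_hit_rank and r.first_hit_rank <= n)
        p = tp / (generated * n) if generated else 0.0
        rcl = tp / total_truths if total_truths else 0.0
        rows.append({"n": n, "num_con": hits, "micro_precision": p,
                     "micro_recall": rcl, "micro_f": _f_score(p, rcl)})
    return pd.DataFrame(rows)


def compare_algorithms(report_a, report_b) -> int | None:
    """Relative macro-F improvement of b over a, as a rounded percentage.

    Arguments may be :class:`EvaluationReport` objects, plain macro-F
    numbers, or sequences of either (averaged, e.g. over two datasets).
    Returns ``None`` when the baseline F is 0 (undefined).
    """
    def f_of(x) -> float:
        if isinstance(x, EvaluationReport):
            return x.macro.f_score
        if isinstance(x, (list, tuple)):
            return sum(f_of(v) for v in x) / len(x)
        return float(x)

    f_a, f_b = f_of(report_a), f_of(report_b)
    if f_a == 0:
        return None
    return round((f_b - f_a) / f_a * 100)


def paired_hit_test(hits_a: Sequence[bool], hits_b: Sequence[bool]) -> float:
    """Exact McNemar test on paired per-concept hit indicators.

    Provided as optional tooling for comparing two algorithms on the same
    concepts; this specific test is a package choice, not part of the
    evaluation framework above.  Returns the two-sided p-value of the
    exact binomial test on discordant pairs.
    """
    if len(hits_a) != len(hits_b):
        raise ValueError("paired indicator sequences must have equal length")
    b01 = sum(1 for x, y in zip(hits_a, hits_b) if not x and y)
    b10 = sum(1 for x, y in zip(hits_a, hits_b) if x and not y)
    m = b01 + b10
    if m == 0:
        return 1.0
    k = min(b01, b10)
    tail = sum(math.comb(m, i) for i in range(k + 1)) / 2.0**m
    return min(1.0, 2 * tail)
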