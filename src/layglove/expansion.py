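"""Corpus expansion: insert relational synsets around seed-term occurrences.

Scored related terms are ranked by similarity, capped (default: the ten
most similar), and split into a left subset X1 and a right subset X2.
Every occurrence of the seed ``s`` in the corpus is then rewritten
``... w  X1  s  X2  w' ...`` so that the seed's co-occurrence contexts are
enriched with lexicon knowledge before embedding training.  Only original
corpus positions are scanned — inserted tokens are never themselves
expanded — and deleting all inserted tokens recovers the original corpus
exactly.

Two split modes are provided.  ``roundrobin`` alternates assignment
left, right, left, ... down the ranked list, which balances the total
similarity carried by each side; ``halves`` places the top half
contiguously on the left.  Both orderings are useful: round-robin balances
weight, halves keeps the most similar items adjacent to the seed on one
side.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .lexicon import RelatedTerm, RelationKind
from .textprep import TokenizedCorpus

__all__ = ["ExpansionPlan", "ExpandedCorpus", "rank_and_split", "expand_corpus",
           "build_plans", "write_plans", "read_plans"]


@dataclass(frozen=True)
class ExpansionPlan:
    seed_term: str
    kind: RelationKind
    left: tuple[str, ...]
    right: tuple[str, ...]
    cap: int = 10

    def __post_init__(self) -> None:
        if len(self.left) + len(self.right) > self.cap:
            raise ValueError("plan exceeds its cap")
        if set(self.left) & set(self.right):
            raise ValueError("left and right subsets must be disjoint")


@dataclass
class ExpandedCorpus:
    documents: list[list[str]]
    expansion_log: Counter = field(default_factory=Counter)

    @property
    def corpus(self) -> TokenizedCorpus:
        return TokenizedCorpus(self.documents)


def rank_and_split(
    scored: Sequence[RelatedTerm],
    cap: int = 10,
    mode: str = "roundrobin",
) -> tuple[list[str], list[str]]:
    """Sort by descending score, truncate to ``cap``, split left/right.

    Ties are broken lexicographically by surface so the ranking is
    deterministic.  ``roundrobin`` assigns items alternately left, right,
    left, ...; ``halves`` puts the first ``ceil(k/2)`` items left.
    """
    if cap < 0:
        raise ValueError("cap must be non-negative")
    if mode not in ("roundrobin", "halves"):
        raise ValueError(f"unknown split mode {mode!r}")
    ranked = sorted(scored, key=lambda t: (-t.score, t.surface))[:cap]
    surfaces = [t.surface for t in ranked]
    if mode == "halves":
        half = (len(surfaces) + 1) // 2
        return surfaces[:half], surfaces[half:]
    return surfaces[0::2], surfaces[1::2]


def expand_corpus(
    corpus: TokenizedCorpus,
    plans: Mapping[str, ExpansionPlan],
) -> ExpandedCorpus:
    """Rewrite every planned seed occurrence with its X1/X2 insertions.

    The token count of the result equals the original count plus, for each
    seed, occurrences x (|X1| + |X2|); non-seed tokens are untouched.
    """
    log: Counter = Counter()
    out_docs: list[list[str]] = []
    for doc in corpus.documents:
        out: list[str] = []
        for tok in doc:
            plan = plans.get(tok)
            if plan is None:
                out.append(tok)
            else:
                out.extend(plan.left)
                out.append(tok)
                out.extend(plan.right)
                log[tok] += 1
        out_docs.append(out)
    return ExpandedCorpus(out_docs, log)


def build_plans(
    seeds: Iterable[str],
    kind: RelationKind,
    resource,
    cap: int = 10,
    mode: str = "roundrobin",
) -> dict[str, ExpansionPlan]:
    """One merged plan per distinct seed surface.

    A term seeding several concepts is expanded once: relation lists from
    all its senses are unioned (which :func:`layglove.lexicon.fetch_related`
    already does) before ranking, so no insertion is double-counted.
    """
    from .lexicon import fetch_related

    plans: dict[str, ExpansionPlan] = {}
    for seed in sorted(set(seeds)):
        related = fetch_related(seed, kind, resource)
        if not related:
            continue
        left, right = rank_and_split(related, cap=cap, mode=mode)
        plans[seed] = ExpansionPlan(seed, kind, tuple(left), tuple(right), cap=cap)
    return plans


def write_plans(plans: Mapping[str, ExpansionPlan], path: str | Path) -> None:
    payload = {
        seed: {"kind": p.kind.value, "left": list(p.left), "right": list(p.right),
               "cap": p.cap}
        for seed, p in sorted(plans.items())
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_plans(path: str | Path) -> dict[str, ExpansionPlan]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {
        seed: ExpansionPlan(seed, RelationKind(d["kind"]), tuple(d["left"]),
                            tuple(d["right"]), cap=d.get("cap", 10))
        for seed, d in payload.items()
    }
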