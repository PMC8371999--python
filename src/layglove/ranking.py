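"""Candidate synonym ranking by cosine similarity to a seed vector.

The ranking is an exhaustive scan of the model vocabulary: for a seed term
s with vector v_s, every other token's vector is compared with
cos(v_s, v) = v_s . v / (|v_s| |v|) and the top n become the candidate
list.  Cosine lies in [-1, 1]; negative-scored candidates are retained and
ranked (clipping to [0, 1] would discard ordering information among
dissimilar words).  Other seed terms of the same concept are deliberately
*not* excluded — held-out synonyms must be retrievable for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .glove import EmbeddingModel

__all__ = ["CandidateList", "cosine_similarity", "top_candidates", "write_candidates"]


@dataclass(frozen=True)
class CandidateList:
    """Ranked (token, score) candidates for one seed term.

    Scores are non-increasing, the seed never appears, and the length is
    at most the requested ``n``.
    """

    seed_term: str
    candidates: tuple[tuple[str, float], ...]
    n: int


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """cos(v1, v2) in [-1, 1]; zero-norm vectors are a domain error."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal dimension")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(v1, v2) / (n1 * n2))


def top_candidates(
    model: EmbeddingModel,
    seed: str,
    n: int = 10,
    exclusions: Iterable[str] = (),
) -> CandidateList | None:
    """Top-``n`` vocabulary tokens by cosine similarity to ``seed``.

    Returns ``None`` when the seed is out of vocabulary ("no list
    generated" — the caller's NumCon accounting, not an exception).  Ties
    are broken lexicographically, so results are deterministic.
    """
    if seed not in model:
        return None
    excluded = set(exclusions) | {seed}
    sv = model.vector(seed)
    sn = np.linalg.norm(sv)
    if sn == 0.0:
        return None
    norms = np.linalg.norm(model.vectors, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = (model.vectors @ sv) / (norms * sn)
    scored = [
        (tok, float(sims[i]))
        for tok, i in model.index.items()
        if tok not in excluded and norms[i] > 0.0
    ]
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return CandidateList(seed, tuple(scored[:n]), n)


def write_candidates(
    lists: Mapping[str, CandidateList] | Sequence[CandidateList],
    path: str | Path,
) -> None:
    """TSV export: `seed<TAB>rank<TAB>candidate<TAB>score`."""
    if isinstance(lists, Mapping):
        lists = list(lists.values())
    with open(path, "w", encoding="utf-8") as fh:
        for cl in sorted(lists, key=lambda c: c.seed_term):
            for rank, (tok, score) in enumerate(cl.candidates, start=1):
                fh.write(f"{cl.seed_term}\t{rank}\t{tok}\t{score:.6f}\n")
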