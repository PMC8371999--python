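"""Relational synsets (synonyms, hyponyms, hypernyms) behind a pluggable
lexical-resource contract, with Resnik information-content similarity.

A :class:`LexicalResource` exposes word senses, their lemma surfaces, a
sense taxonomy with an information-content (IC) table, and hyponym /
hypernym links between senses.  The production analogue is WordNet (any
adapter implementing the protocol can be plugged in); the package bundles a
small deterministic synthetic resource (``data/toy_lexicon.json``) whose
``headache`` entry exercises every relation kind.

Polysemy is handled without disambiguation: relations are collected as the
union over all senses of the query term, and a candidate's similarity to
the seed is the maximum Resnik score over all (seed sense, candidate sense)
pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

from ._stem import get_stemmer

__all__ = [
    "RelationKind",
    "RelatedTerm",
    "LexicalResource",
    "ToyLexicon",
    "SenseNotFoundError",
    "fetch_related",
    "resnik_score",
    "score_against_seed",
    "load_bundled_lexicon",
]


class RelationKind(Enum):
    SYNONYM = "synonym"
    HYPONYM = "hyponym"
    HYPERNYM = "hypernym"


@dataclass(frozen=True)
class RelatedTerm:
    """A lexicon entry related to a query term.

    ``surface`` is a single token; multi-word lemmas are joined with
    underscores (``dead_weight``).  ``score`` is the Resnik similarity to
    the query term (0 until filled by :func:`score_against_seed`).
    """

    surface: str
    kind: RelationKind
    score: float = 0.0
    sense_id: str = ""


@runtime_checkable
class LexicalResource(Protocol):
    """Behavioural contract a lexicon adapter must satisfy.

    Implementations must be pure and deterministic for a fixed
    ``version_tag`` and return empty sequences for unknown terms.
    """

    version_tag: str
    ic: Mapping[str, float]
    taxonomy: Mapping[str, str | None]

    def senses_of(self, term: str) -> Sequence[str]: ...

    def lemmas(self, sense: str) -> Sequence[str]: ...

    def related_senses(self, sense: str, kind: RelationKind) -> Sequence[str]: ...


class SenseNotFoundError(LookupError):
    pass


class ToyLexicon:
    """Deterministic in-memory lexical resource loaded from JSON.

    File format::

        {"version": "...",
         "taxonomy": {sense: parent-or-null},
         "ic": {sense: float},
         "lemmas": {sense: [surface, ...]},
         "relations": {sense: {"hyponyms": [...], "hypernyms": [...]}}}

    Lemma surfaces are stemmed on load (each underscore-separated component
    independently) so that inserted tokens unify with a stemmed corpus
    vocabulary; pass ``stemmer_id="identity"`` to keep raw surfaces.
    """

    def __init__(self, data: Mapping, stemmer_id: str = "snowball-english") -> None:
        stem = get_stemmer(stemmer_id)
        self._stem_surface = lambda s: "_".join(stem(p) for p in s.split("_"))
        self.taxonomy: dict[str, str | None] = dict(data["taxonomy"])
        self.ic: dict[str, float] = {k: float(v) for k, v in data["ic"].items()}
        self._lemmas: dict[str, list[str]] = {
            sense: [self._stem_surface(s.lower()) for s in surfaces]
            for sense, surfaces in data["lemmas"].items()
        }
        self._relations: dict[str, dict[str, list[str]]] = {
            sense: {k: list(v) for k, v in rel.items()}
            for sense, rel in data.get("relations", {}).items()
        }
        self._index: dict[str, list[str]] = {}
        for sense in sorted(self._lemmas):
            for surface in self._lemmas[sense]:
                self._index.setdefault(surface, []).append(sense)
        self.version_tag = f"{data.get('version', 'toy')}+{stemmer_id}"

    @classmethod
    def from_file(cls, path: str | Path, stemmer_id: str = "snowball-english") -> "ToyLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh), stemmer_id=stemmer_id)

    def senses_of(self, term: str) -> Sequence[str]:
        return tuple(self._index.get(term, ()))

    def lemmas(self, sense: str) -> Sequence[str]:
        return tuple(self._lemmas.get(sense, ()))

    def related_senses(self, sense: str, kind: RelationKind) -> Sequence[str]:
        rel = self._relations.get(sense, {})
        key = {RelationKind.HYPONYM: "hyponyms", RelationKind.HYPERNYM: "hypernyms"}
        if kind is RelationKind.SYNONYM:
            return (sense,)  # synonyms are co-lemmas of the same sense
        return tuple(rel.get(key[kind], ()))


def load_bundled_lexicon(stemmer_id: str = "snowball-english") -> ToyLexicon:
    """Load the packaged synthetic miniature lexicon."""
    text = resources.files("layglove.data").joinpath("toy_lexicon.json").read_text("utf-8")
    return ToyLexicon(json.loads(text), stemmer_id=stemmer_id)


def resnik_score(
    sense_a: str,
    sense_b: str,
    ic: Mapping[str, float],
    taxonomy: Mapping[str, str | None],
) -> float:
    """Information content of the most informative common ancestor.

    A sense is its own ancestor, so ``resnik(a, a) == ic[a]``.  Symmetric.
    """
    def ancestors(sense: str) -> list[str]:
        if sense not in taxonomy:
            raise SenseNotFoundError(f"sense {sense!r} not in taxonomy")
        chain, cur = [], sense
        seen = set()
        while cur is not None:
            if cur in seen:  # defensive: cyclic taxonomy
                break
            seen.add(cur)
            chain.append(cur)
            cur = taxonomy.get(cur)
        return chain

    common = set(ancestors(sense_a)) & set(ancestors(sense_b))
    if not common:
        return 0.0
    return max(ic.get(s, 0.0) for s in common)


def fetch_related(
    term: str,
    kind: RelationKind,
    resource: LexicalResource,
) -> list[RelatedTerm]:
    """All lemmas related to ``term`` through ``kind``, scored and deduped.

    Collects the union over every sense of ``term``, excludes ``term``
    itself, scores each candidate with :func:`score_against_seed`, and
    collapses duplicate surfaces keeping the maximum score.  Unknown terms
    yield an empty list.
    """
    raw: list[RelatedTerm] = []
    for sense in resource.senses_of(term):
        for rel_sense in resource.related_senses(sense, kind):
            for surface in resource.lemmas(rel_sense):
                if surface != term:
                    raw.append(RelatedTerm(surface, kind, sense_id=rel_sense))
    scored = score_against_seed(term, raw, resource)
    best: dict[str, RelatedTerm] = {}
    for cand in scored:
        cur = best.get(cand.surface)
        if cur is None or cand.score > cur.score:
            best[cand.surface] = cand
    return [best[s] for s in sorted(best)]


def score_against_seed(
    seed: str,
    candidates: Sequence[RelatedTerm],
    resource: LexicalResource,
) -> list[RelatedTerm]:
    """Fill each candidate's score with its Resnik similarity to the seed.

    The score is the maximum over all (seed sense, candidate sense) pairs;
    a candidate surface absent from the lemma index falls back to the sense
    it was collected from.
    """
    seed_senses = resource.senses_of(seed)
    out = []
    for cand in candidates:
        cand_senses = resource.senses_of(cand.surface) or (
            (cand.sense_id,) if cand.sense_id else ()
        )
        score = 0.0
        for s in seed_senses:
            for c in cand_senses:
                score = max(
                    score, resnik_score(s, c, resource.ic, resource.taxonomy)
                )
        out.append(replace(cand, score=score))
    return out
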