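"""Concept/layman-term ground truth: loading, filtering, seed assignment.

A ground-truth dataset maps professional medical concepts (keyed by CUI,
the UMLS Concept Unique Identifier) to the stemmed unigram lay terms people
actually use for them.  For evaluation, one term per concept is drawn at
random as the *seed* used to query the embedding space; the remainder are
held out as the synonyms the system is asked to rediscover.

Filtering rules applied by :func:`build_ground_truth`:

* only unigram terms (no whitespace) are considered, and only concepts
  whose preferred name is itself a unigram;
* terms are stemmed and de-duplicated; a term equal to the stemmed
  preferred name is dropped (it is the professional word, not a lay one);
* a term must occur in the preprocessed corpus strictly more than
  ``min_freq`` times (default 100);
* a concept survives only with at least ``min_terms`` surviving terms
  (default 2: one seed plus at least one held-out synonym).
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from ._stem import get_stemmer

__all__ = [
    "ConceptRecord",
    "SeedAssignment",
    "MappingParseError",
    "load_concept_mappings",
    "build_ground_truth",
    "assign_seeds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConceptRecord:
    cui: str
    preferred_name: str
    layman_terms: frozenset[str]


@dataclass(frozen=True)
class SeedAssignment:
    cui: str
    seed_term: str
    held_out: frozenset[str]

    def __post_init__(self) -> None:
        if self.seed_term in self.held_out or not self.held_out:
            raise ValueError("seed term must be disjoint from a non-empty held-out set")


class MappingParseError(ValueError):
    """A concept-mapping TSV row did not have exactly three fields."""


def load_concept_mappings(source: IO[str] | str | Path) -> list[ConceptRecord]:
    """Parse `CUI<TAB>concept_name<TAB>term` rows, grouped by CUI.

    Multiple rows per CUI accumulate terms; duplicate rows deduplicate.
    The result is sorted by CUI so it is independent of row order.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return load_concept_mappings(fh)
    names: dict[str, str] = {}
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(source, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise MappingParseError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        cui, name, term = fields
        names.setdefault(cui, name)
        terms.setdefault(cui, set()).add(term)
    return [
        ConceptRecord(cui=cui, preferred_name=names[cui], layman_terms=frozenset(terms[cui]))
        for cui in sorted(names)
    ]


def build_ground_truth(
    records: Iterable[ConceptRecord],
    freqs: Mapping[str, int],
    min_freq: int = 100,
    min_terms: int = 2,
    stemmer_id: str = "snowball-english",
) -> list[ConceptRecord]:
    """Filter raw concept records down to the evaluable ground-truth dataset.

    ``freqs`` must come from the same preprocessed (unexpanded) corpus the
    experiment will train on, so the frequency filter matches what the
    embedding model can actually see.  Returns records sorted by CUI; an
    exclusion summary is logged rather than raised.
    """
    stem = get_stemmer(stemmer_id)
    kept: list[ConceptRecord] = []
    stats = {"concepts_in": 0, "multiword_name": 0, "too_few_terms": 0, "terms_dropped": 0}
    for rec in sorted(records, key=lambda r: r.cui):
        stats["concepts_in"] += 1
        if len(rec.preferred_name.split()) != 1:
            stats["multiword_name"] += 1
            continue
        name_stem = stem(rec.preferred_name.lower())
        surviving = set()
        for term in rec.layman_terms:
            if len(term.split()) != 1:
                stats["terms_dropped"] += 1
                continue
            t = stem(term.lower())
            if t == name_stem or freqs.get(t, 0) <= min_freq:
                stats["terms_dropped"] += 1
                continue
            surviving.add(t)
        if len(surviving) >= min_terms:
            kept.append(
                ConceptRecord(rec.cui, rec.preferred_name, frozenset(surviving))
            )
        else:
            stats["too_few_terms"] += 1
    logger.info(
        "ground truth: %d/%d concepts kept (%d multi-word names, %d with too few "
        "terms, %d terms dropped)",
        len(kept), stats["concepts_in"], stats["multiword_name"],
        stats["too_few_terms"], stats["terms_dropped"],
    )
    return kept


def assign_seeds(dataset: Iterable[ConceptRecord], rng_seed: int) -> list[SeedAssignment]:
    """Pick one seed term per concept at random; the rest are held out.

    A single RNG stream seeded once walks the concepts in sorted CUI order,
    so assignments are reproducible regardless of input order.
    """
    rng = random.Random(rng_seed)
    assignments = []
    for rec in sorted(dataset, key=lambda r: r.cui):
        terms = sorted(rec.layman_terms)
        if len(terms) < 2:
            raise ValueError(f"concept {rec.cui} has fewer than 2 terms")
        seed = rng.choice(terms)
        assignments.append(
            SeedAssignment(rec.cui, seed, frozenset(t for t in terms if t != seed))
        )
    return assignments


# ---------------------------------------------------------------------------
# serialization

def write_ground_truth(dataset: Iterable[ConceptRecord], path: str | Path,
                       stats: Mapping[str, int] | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in sorted(dataset, key=lambda r: r.cui):
            for term in sorted(rec.layman_terms):
                fh.write(f"{rec.cui}\t{term}\n")
    if stats is not None:
        path.with_suffix(path.suffix + ".stats.json").write_text(json.dumps(stats, indent=2))


def write_assignments(assignments: Iterable[SeedAssignment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in sorted(assignments, key=lambda a: a.cui):
            fh.write(f"{a.cui}\t{a.seed_term}\t{','.join(sorted(a.held_out))}\n")


def read_assignments(path: str | Path) -> Iterator[SeedAssignment]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                cui, seed, held = line.rstrip("\n").split("\t")
                yield SeedAssignment(cui, seed, frozenset(held.split(",")))
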