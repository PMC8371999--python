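"""Seeded synthetic benchmarks: corpus + concept mappings + toy lexicon.

The generator plants the statistical structure the embedding pipeline is
built to exploit — words appearing in similar contexts are similar in
meaning — in its minimal identifiable form: each medical concept owns a
small multinomial of topic (context) tokens, and its synonym tokens
substitute for one another in identical context slots.  Documents about a
concept interleave its synonyms, its context tokens, and shared background
noise.  Every planted synonym is guaranteed a corpus frequency strictly
above ``min_planted_freq``, so the ground-truth frequency filter (> 100 by
default) admits the whole planted vocabulary when ``min_planted_freq >=
100``.

The accompanying toy lexicon deliberately exposes only ``lexicon_coverage``
of each synonym group (plus a planted two-level taxonomy providing
hyponym/hypernym links), so corpus-derived and lexicon-derived true
positives remain distinguishable in experiments.

What this emulates — and what it does not: token co-occurrence statistics
with planted synonymy are faithful; real lay health text additionally has
misspellings, multi-word terms, topic drift and heavy-tailed vocabulary,
none of which are simulated.  Pipeline results on these benchmarks
demonstrate mechanism, not clinical-corpus performance.

All generated tokens are lowercase alphabetic, at least 3 characters,
stem-stable (stemming maps them to themselves) and outside the stopword
lists, so preprocessing passes them through unchanged.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._stem import snowball_english
from ._stopwords import DEFAULT_DOMAIN_STOPWORDS, ENGLISH_STOPWORDS
from .lexicon import ToyLexicon
from .textprep import RawDocument

__all__ = ["SynthConfig", "SynthBenchmark", "generate_benchmark"]

_CONSONANTS = "bcdfghjklmnpqrstvz"
_VOWELS = "aeiou"
_STOP = ENGLISH_STOPWORDS | DEFAULT_DOMAIN_STOPWORDS


@dataclass(frozen=True)
class SynthConfig:
    """Benchmark shape; defaults give a desk-scale pipeline exercise.

    ``min_planted_freq`` is a strict lower bound on every planted
    synonym's corpus frequency; generation fails up front when the token
    budget (docs x doc_length) cannot honour it.
    """

    n_concepts: int = 20
    synonyms_per_concept: int = 3
    context_tokens_per_concept: int = 8
    background_vocab: int = 150
    docs: int = 800
    doc_length: int = 40
    lexicon_coverage: float = 0.6
    min_planted_freq: int = 101
    rng_seed: int = 13
    synonym_rate: float = 0.3
    context_rate: float = 0.45

    def __post_init__(self) -> None:
        if (
            min(self.n_concepts, self.context_tokens_per_concept,
                self.background_vocab, self.docs, self.doc_length) < 1
            or self.synonyms_per_concept < 2
            or not (0.0 <= self.lexicon_coverage <= 1.0)
        ):
            raise ValueError("invalid synthetic benchmark configuration")


@dataclass
class SynthBenchmark:
    documents: list[RawDocument]
    concept_tsv: str
    lexicon: ToyLexicon
    synonyms: dict[str, list[str]] = field(default_factory=dict)  # cui -> tokens
    contexts: dict[str, list[str]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        corpus = out / "corpus.txt"
        with open(corpus, "w", encoding="utf-8") as fh:
            for doc in self.documents:
                fh.write(doc.text + "\n")
        mappings = out / "concepts.tsv"
        mappings.write_text(self.concept_tsv, encoding="utf-8")
        lexicon = out / "lexicon.json"
        lexicon.write_text(self.lexicon_json(), encoding="utf-8")
        return {"corpus": corpus, "mappings": mappings, "lexicon": lexicon}

    def lexicon_json(self) -> str:
        import json

        lx = self.lexicon
        return json.dumps(
            {
                "version": lx.version_tag.split("+")[0],
                "taxonomy": lx.taxonomy,
                "ic": lx.ic,
                "lemmas": {s: list(lx.lemmas(s)) for s in lx.taxonomy},
                "relations": {
                    s: {
                        "hyponyms": list(lx._relations.get(s, {}).get("hyponyms", [])),
                        "hypernyms": list(lx._relations.get(s, {}).get("hypernyms", [])),
                    }
                    for s in lx.taxonomy
                },
            },
            indent=2,
        )


def _make_tokens(rng: random.Random, count: int, taken: set[str]) -> list[str]:
    """Invent stem-stable pseudo-words the preprocessing pipeline keeps."""
    out: list[str] = []
    while len(out) < count:
        n_syll = rng.randint(2, 3)
        tok = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
        ) + rng.choice(_CONSONANTS)
        if tok in taken or tok in _STOP or len(tok) < 3:
            continue
        if snowball_english(tok) != tok:
            continue
        taken.add(tok)
        out.append(tok)
    return out


def generate_benchmark(config: SynthConfig) -> SynthBenchmark:
    """Build a fully deterministic corpus/mapping/lexicon triple.

    Documents are assigned to concepts round-robin; each document draws
    every slot independently: a synonym of its concept with probability
    ``synonym_rate``, a concept context token with ``context_rate``, else
    a background token.  After sampling, deficient synonyms are topped up
    with additional concept documents so the frequency guarantee is exact
    (checked by recount before returning).
    """
    rng = random.Random(config.rng_seed)
    need = config.n_concepts * config.synonyms_per_concept * (config.min_planted_freq + 1)
    budget = config.docs * config.doc_length
    if need > budget:
        raise ValueError(
            f"infeasible frequency guarantee: need >= {need} synonym tokens "
            f"but the corpus budget is {budget}"
        )

    taken: set[str] = set()
    cuis = [f"C{k:07d}" for k in range(1, config.n_concepts + 1)]
    names = dict(zip(cuis, _make_tokens(rng, config.n_concepts, taken)))
    synonyms = {
        cui: _make_tokens(rng, config.synonyms_per_concept, taken) for cui in cuis
    }
    contexts = {
        cui: _make_tokens(rng, config.context_tokens_per_concept, taken) for cui in cuis
    }
    background = _make_tokens(rng, config.background_vocab, taken)
    domain_tokens = _make_tokens(rng, 4, taken)
    hypo_tokens = dict(zip(cuis, _make_tokens(rng, config.n_concepts, taken)))

    docs_tokens: list[list[str]] = []
    for d in range(config.docs):
        cui = cuis[d % config.n_concepts]
        doc = []
        for _ in range(config.doc_length):
            u = rng.random()
            if u < config.synonym_rate:
                doc.append(rng.choice(synonyms[cui]))
            elif u < config.synonym_rate + config.context_rate:
                doc.append(rng.choice(contexts[cui]))
            else:
                doc.append(rng.choice(background))
        docs_tokens.append(doc)

    # Top up any synonym that fell short of the guarantee.
    counts: dict[str, int] = {}
    for doc in docs_tokens:
        for t in doc:
            counts[t] = counts.get(t, 0) + 1
    for cui in cuis:
        for syn in synonyms[cui]:
            while counts.get(syn, 0) <= config.min_planted_freq:
                doc = []
                for i in range(config.doc_length):
                    doc.append(syn if i % 2 == 0 else rng.choice(contexts[cui]))
                docs_tokens.append(doc)
                for t in doc:
                    counts[t] = counts.get(t, 0) + 1

    for cui in cuis:
        for syn in synonyms[cui]:
            assert counts[syn] > config.min_planted_freq

    documents = [
        RawDocument(doc_id=f"synth:{i}", text=" ".join(doc))
        for i, doc in enumerate(docs_tokens)
    ]

    tsv_lines = []
    for cui in cuis:
        for syn in synonyms[cui]:
            tsv_lines.append(f"{cui}\t{names[cui]}\t{syn}")
    concept_tsv = "\n".join(tsv_lines) + "\n"

    lexicon = _build_lexicon(config, rng, cuis, synonyms, domain_tokens, hypo_tokens)
    return SynthBenchmark(documents, concept_tsv, lexicon,
                          synonyms=dict(synonyms), contexts=dict(contexts))


def _build_lexicon(
    config: SynthConfig,
    rng: random.Random,
    cuis: Sequence[str],
    synonyms: dict[str, list[str]],
    domain_tokens: Sequence[str],
    hypo_tokens: dict[str, str],
) -> ToyLexicon:
    taxonomy: dict[str, str | None] = {"root.n.01": None}
    ic: dict[str, float] = {"root.n.01": 0.0}
    lemmas: dict[str, list[str]] = {"root.n.01": []}
    relations: dict[str, dict[str, list[str]]] = {}
    for g, tok in enumerate(domain_tokens):
        sense = f"domain{g}.n.01"
        taxonomy[sense] = "root.n.01"
        ic[sense] = 1.0
        lemmas[sense] = [tok]
    for k, cui in enumerate(cuis):
        sense = f"{cui.lower()}.n.01"
        domain = f"domain{k % len(domain_tokens)}.n.01"
        taxonomy[sense] = domain
        ic[sense] = 3.0 + rng.random()
        n_cov = round(config.lexicon_coverage * len(synonyms[cui]))
        covered = sorted(rng.sample(synonyms[cui], n_cov))
        lemmas[sense] = covered
        hypo_sense = f"{cui.lower()}.hypo.n.01"
        taxonomy[hypo_sense] = sense
        ic[hypo_sense] = 6.0
        lemmas[hypo_sense] = [hypo_tokens[cui]]
        relations[sense] = {"hyponyms": [hypo_sense], "hypernyms": [domain]}
        relations[hypo_sense] = {"hyponyms": [], "hypernyms": [sense]}
    data = {
        "version": f"synth-{config.rng_seed}",
        "taxonomy": taxonomy,
        "ic": ic,
        "lemmas": lemmas,
        "relations": relations,
    }
    # tokens are stem-stable, so the identity stemmer keeps surfaces aligned
    # with the preprocessed corpus vocabulary
    return ToyLexicon(data, stemmer_id="identity")
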