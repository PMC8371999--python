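"""Corpus normalisation: raw documents to stemmed, filtered token streams.

The pipeline applies, in a fixed order: lowercase, strip punctuation (tokens
are maximal runs of alphanumeric characters, with apostrophes deleted rather
than split on), drop tokens containing digits, drop stopwords and
domain-specific stopwords, stem, and finally drop tokens shorter than
``min_token_len``.  Stemming before the length filter matters: a lay term
such as ``fatigued`` stems to ``fatigu`` (6 characters) and survives, while
stemming after filtering would have dropped nothing either way — but e.g.
``ageing`` -> ``age`` (3) is kept only because the filter sees the stem.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from ._stem import get_stemmer
from ._stopwords import DEFAULT_DOMAIN_STOPWORDS, ENGLISH_STOPWORDS

__all__ = [
    "RawDocument",
    "TokenizedCorpus",
    "preprocess_corpus",
    "term_frequencies",
    "read_documents",
    "write_corpus",
    "read_corpus",
    "write_vocabulary",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_DIGIT_RE = re.compile(r"\d")


@dataclass(frozen=True)
class RawDocument:
    """One unprocessed document (e.g. a forum post)."""

    doc_id: str
    text: str


@dataclass
class TokenizedCorpus:
    """Preprocessed token sequences plus their vocabulary frequencies.

    ``vocabulary`` always equals a recount over ``documents``; it is carried
    so downstream frequency filters need not re-scan the corpus.
    """

    documents: list[list[str]]
    vocabulary: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.vocabulary:
            self.vocabulary = Counter(t for doc in self.documents for t in doc)

    @property
    def n_tokens(self) -> int:
        return sum(self.vocabulary.values())

    def recount(self) -> Counter:
        """Brute-force recount of the vocabulary (invariant check)."""
        return Counter(t for doc in self.documents for t in doc)


def _normalize_stopwords(words: Iterable[str]) -> frozenset:
    # Apostrophes are deleted during tokenization, so "isn't" must be
    # matched as "isnt".
    return frozenset(w.replace("'", "") for w in words)


def preprocess_corpus(
    docs: Iterable[RawDocument],
    stopwords: Iterable[str] = ENGLISH_STOPWORDS,
    domain_stopwords: Iterable[str] = DEFAULT_DOMAIN_STOPWORDS,
    min_token_len: int = 3,
    stemmer_id: str = "snowball-english",
) -> TokenizedCorpus:
    """Normalise raw documents into stemmed, filtered token streams.

    Parameters
    ----------
    docs:
        Raw documents; empty documents yield empty token sequences (kept, so
        document count is preserved).
    stopwords, domain_stopwords:
        Lowercase words removed before stemming.  The defaults are the
        bundled English list and {test, doctor, symptom, physician}.
    min_token_len:
        Minimum surviving token length, applied to the *stemmed* form.
    stemmer_id:
        Identifier resolved via :func:`layglove._stem.get_stemmer`;
        unknown identifiers raise ``UnknownStemmerError``.
    """
    stem = get_stemmer(stemmer_id)
    stop = _normalize_stopwords(stopwords) | _normalize_stopwords(domain_stopwords)
    documents: list[list[str]] = []
    for doc in docs:
        raw = doc.text.lower().replace("'", "")
        tokens = []
        for tok in _TOKEN_RE.findall(raw):
            if _DIGIT_RE.search(tok):
                continue
            if tok in stop:
                continue
            stemmed = stem(tok)
            if len(stemmed) < min_token_len:
                continue
            tokens.append(stemmed)
        documents.append(tokens)
    return TokenizedCorpus(documents)


def term_frequencies(corpus: TokenizedCorpus) -> Mapping[str, int]:
    """Token -> corpus frequency for a preprocessed corpus."""
    return dict(corpus.vocabulary)


# ---------------------------------------------------------------------------
# I/O: one document per line; vocabulary as `token<TAB>count`.

def read_documents(path: str | Path) -> Iterator[RawDocument]:
    """Read raw documents from a UTF-8 text file, one document per line.

    If ``path`` is a directory, every ``*.txt`` file in it (sorted by name)
    is read the same way; doc ids are ``<filename>:<lineno>``.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    for f in files:
        with open(f, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                yield RawDocument(doc_id=f"{f.name}:{i}", text=line.rstrip("\n"))


def write_corpus(corpus: TokenizedCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(" ".join(doc) + "\n")


def read_corpus(path: str | Path) -> TokenizedCorpus:
    """Read an already-preprocessed corpus (space-joined tokens per line)."""
    documents = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            documents.append(line.split())
    return TokenizedCorpus(documents)


def write_vocabulary(vocab: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for token in sorted(vocab):
            fh.write(f"{token}\t{vocab[token]}\n")


def read_vocabulary(path: str | Path) -> dict[str, int]:
    vocab: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                token, count = line.rstrip("\n").split("\t")
                vocab[token] = int(count)
    return vocab
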