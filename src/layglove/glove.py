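"""Global co-occurrence counting and log-bilinear embedding training.

The model is the weighted least-squares objective

    J = sum_{ij : X_ij > 0} f(X_ij) (w_i . w~_j + b_i + b~_j - log X_ij)^2

with f(x) = (x / x_max)^alpha for x < x_max, else 1, minimised by AdaGrad
stochastic updates over the nonzero entries in shuffled order.  The
co-occurrence matrix X is symmetric: for every unordered token pair within
``window`` positions of each other (windows never cross document
boundaries) a weight of 1 (``flat``) or 1/distance (``inverse-distance``)
is accumulated.  Exported vectors are w + w~ by default, the combination
that performs best on word-similarity tasks; ``combine="w"`` exports the
main vectors alone.

Training is bitwise reproducible for a fixed ``rng_seed``: initialisation,
per-epoch shuffles, and the sequential update order are all derived from a
single seeded generator, and the inner loop is compiled (numba) so the
floating-point evaluation order is fixed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
from numba import njit

__all__ = [
    "CooccurrenceMatrix",
    "TrainingConfig",
    "EmbeddingModel",
    "EmbeddingFormatError",
    "build_cooccurrence",
    "train_embeddings",
    "save_embeddings",
    "load_embeddings",
]

logger = logging.getLogger(__name__)

WEIGHTINGS = ("flat", "inverse-distance")


@dataclass
class CooccurrenceMatrix:
    """Sparse symmetric co-occurrence weights over an indexed vocabulary.

    ``entries`` stores each unordered pair once under the canonical key
    ``(min(i,j), max(i,j))``; :meth:`weight` answers either orientation.
    """

    vocab_index: dict[str, int]
    entries: dict[tuple[int, int], float]
    window: int
    weighting: str

    @property
    def tokens(self) -> list[str]:
        out = [""] * len(self.vocab_index)
        for tok, i in self.vocab_index.items():
            out[i] = tok
        return out

    def weight(self, a: str, b: str) -> float:
        i, j = self.vocab_index.get(a), self.vocab_index.get(b)
        if i is None or j is None:
            return 0.0
        return self.entries.get((min(i, j), max(i, j)), 0.0)

    def row(self, a: str) -> dict[str, float]:
        """All nonzero co-occurrence weights involving token ``a``."""
        i = self.vocab_index.get(a)
        if i is None:
            return {}
        toks = self.tokens
        out = {}
        for (p, q), w in self.entries.items():
            if p == i:
                out[toks[q]] = out.get(toks[q], 0.0) + w
            elif q == i:
                out[toks[p]] = out.get(toks[p], 0.0) + w
        return out


def build_cooccurrence(
    documents: Sequence[Sequence[str]],
    window: int,
    weighting: str = "inverse-distance",
) -> CooccurrenceMatrix:
    """One-pass global co-occurrence count around every pivot token.

    For each ordered position pair at distance ``d <= window`` within a
    document, weight 1 (flat) or 1/d (inverse-distance) is added once to
    the unordered pair's entry.  ``window < 1`` is a configuration error.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    vocab_index: dict[str, int] = {}
    for doc in documents:
        for tok in doc:
            if tok not in vocab_index:
                vocab_index[tok] = len(vocab_index)
    entries: dict[tuple[int, int], float] = {}
    inv = weighting == "inverse-distance"
    for doc in documents:
        ids = [vocab_index[t] for t in doc]
        n = len(ids)
        for p in range(n):
            i = ids[p]
            for d in range(1, min(window, n - 1 - p) + 1):
                j = ids[p + d]
                key = (i, j) if i <= j else (j, i)
                entries[key] = entries.get(key, 0.0) + (1.0 / d if inv else 1.0)
    return CooccurrenceMatrix(vocab_index, entries, window, weighting)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the embedding fit.

    Defaults follow the standard GloVe recipe: ``x_max=100``,
    ``alpha=0.75``, initial learning rate 0.05 with AdaGrad per-parameter
    adaptation, vectors initialised uniformly in (-0.5/dim, +0.5/dim).
    """

    dim: int = 100
    epochs: int = 25
    x_max: float = 100.0
    alpha: float = 0.75
    learning_rate: float = 0.05
    rng_seed: int = 13
    combine: str = "sum"  # "sum" -> w + w~ ; "w" -> main vectors only

    def __post_init__(self) -> None:
        if self.dim < 1 or self.epochs < 0 or not (0 < self.alpha <= 1):
            raise ValueError("invalid training configuration")


@dataclass
class EmbeddingModel:
    """Trained (or loaded) word vectors.

    ``vectors`` are the export vectors used for similarity queries.  The
    raw parameters (main/context vectors and biases) are retained after
    training and ``None`` on models loaded from disk.
    """

    tokens: list[str]
    vectors: np.ndarray
    W: np.ndarray | None = None
    W_ctx: np.ndarray | None = None
    b: np.ndarray | None = None
    b_ctx: np.ndarray | None = None
    epoch_losses: list[float] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]


@njit(cache=False)
def _adagrad_epoch(order, rows, cols, logx, fx, W, Wc, b, bc,
                   gW, gWc, gb, gbc, lr):  # pragma: no cover - compiled
    dim = W.shape[1]
    total = 0.0
    for k in order:
        i = rows[k]
        j = cols[k]
        diff = b[i] + bc[j] - logx[k]
        for d in range(dim):
            diff += W[i, d] * Wc[j, d]
        fdiff = fx[k] * diff
        total += 0.5 * fdiff * diff
        for d in range(dim):
            gw = fdiff * Wc[j, d]
            gc = fdiff * W[i, d]
            W[i, d] -= lr * gw / math.sqrt(gW[i, d])
            Wc[j, d] -= lr * gc / math.sqrt(gWc[j, d])
            gW[i, d] += gw * gw
            gWc[j, d] += gc * gc
        b[i] -= lr * fdiff / math.sqrt(gb[i])
        bc[j] -= lr * fdiff / math.sqrt(gbc[j])
        gb[i] += fdiff * fdiff
        gbc[j] += fdiff * fdiff
    return total


def train_embeddings(matrix: CooccurrenceMatrix, config: TrainingConfig) -> EmbeddingModel:
    """Fit the log-bilinear model to the nonzero co-occurrence entries.

    Each symmetric entry is visited in both orientations (i as pivot with j
    as context, and vice versa) once per epoch, in an order reshuffled each
    epoch from the seeded generator.  Mean loss per epoch is recorded on
    the returned model.  An empty matrix yields seeded initial vectors and
    zero loss with a warning.
    """
    tokens = matrix.tokens
    n, dim = len(tokens), config.dim
    rng = np.random.default_rng(config.rng_seed)
    W = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim))
    Wc = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim))
    b = rng.uniform(-0.5 / dim, 0.5 / dim, size=n)
    bc = rng.uniform(-0.5 / dim, 0.5 / dim, size=n)

    pairs = sorted(matrix.entries.items())
    rows_l, cols_l, x_l = [], [], []
    for (i, j), x in pairs:
        if x <= 0.0:
            continue
        rows_l.append(i); cols_l.append(j); x_l.append(x)
        if i != j:
            rows_l.append(j); cols_l.append(i); x_l.append(x)
    m = len(rows_l)
    losses: list[float] = []
    if m == 0:
        logger.warning("empty co-occurrence matrix: returning initialised vectors")
        losses = [0.0] * config.epochs
    else:
        rows = np.asarray(rows_l, dtype=np.int64)
        cols = np.asarray(cols_l, dtype=np.int64)
        x = np.asarray(x_l, dtype=np.float64)
        logx = np.log(x)
        fx = np.where(x < config.x_max, (x / config.x_max) ** config.alpha, 1.0)
        gW = np.ones_like(W)
        gWc = np.ones_like(Wc)
        gb = np.ones_like(b)
        gbc = np.ones_like(bc)
        for _ in range(config.epochs):
            order = rng.permutation(m)
            total = _adagrad_epoch(order, rows, cols, logx, fx, W, Wc, b, bc,
                                   gW, gWc, gb, gbc, config.learning_rate)
            losses.append(total / m)

    vectors = W + Wc if config.combine == "sum" else W.copy()
    return EmbeddingModel(tokens=list(tokens), vectors=vectors, W=W, W_ctx=Wc,
                          b=b, b_ctx=bc, epoch_losses=losses)


# ---------------------------------------------------------------------------
# text I/O

class EmbeddingFormatError(ValueError):
    pass


def save_embeddings(model: EmbeddingModel, dest: IO[str] | str | Path) -> None:
    """Write export vectors as `token v1 ... vd`, one word per line."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            save_embeddings(model, fh)
        return
    for tok, vec in zip(model.tokens, model.vectors):
        dest.write(tok + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def load_embeddings(src: IO[str] | str | Path) -> EmbeddingModel:
    """Read a word-per-line vector file back into a query-only model."""
    if isinstance(src, (str, Path)):
        with open(src, encoding="utf-8") as fh:
            return load_embeddings(fh)
    tokens, rows = [], []
    dim = None
    for lineno, line in enumerate(src, start=1):
        parts = line.split()
        if not parts:
            continue
        vec = [float(v) for v in parts[1:]]
        if dim is None:
            dim = len(vec)
        elif len(vec) != dim:
            raise EmbeddingFormatError(
                f"line {lineno}: expected {dim} components, got {len(vec)}"
            )
        tokens.append(parts[0])
        rows.append(vec)
    vectors = np.asarray(rows, dtype=np.float64) if rows else np.zeros((0, 0))
    return EmbeddingModel(tokens=tokens, vectors=vectors)


def save_cooccurrence(matrix: CooccurrenceMatrix, path: str | Path) -> None:
    """TSV triples `i<TAB>j<TAB>weight` under a '#'-prefixed JSON header."""
    header = {"vocab": matrix.tokens, "window": matrix.window,
              "weighting": matrix.weighting}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        for (i, j), w in sorted(matrix.entries.items()):
            fh.write(f"{i}\t{j}\t{w:.8g}\n")


def load_cooccurrence(path: str | Path) -> CooccurrenceMatrix:
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline().lstrip("#"))
        entries: dict[tuple[int, int], float] = {}
        for line in fh:
            if line.strip():
                i, j, w = line.split("\t")
                entries[(int(i), int(j))] = float(w)
    vocab_index = {t: i for i, t in enumerate(header["vocab"])}
    return CooccurrenceMatrix(vocab_index, entries, header["window"], header["weighting"])
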