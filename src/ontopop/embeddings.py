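"""Skip-gram embeddings, text-format vector I/O, and averaged label vectors.

``train_embeddings`` is a self-contained skip-gram-with-negative-sampling
implementation (single worker, seeded) so training is exactly reproducible
without any external embedding library.  Pre-trained vectors are loaded from
the two common text dialects (word2vec with a count/dim header, GloVe
without).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "EmbeddingTable",
    "LabelVector",
    "VectorFormatError",
    "train_embeddings",
    "load_vectors",
    "write_vectors",
    "label_vector",
]

log = logging.getLogger(__name__)


class VectorFormatError(ValueError):
    """A vector file does not parse in the declared dialect."""


@dataclass
class EmbeddingTable:
    dim: int
    vectors: Dict[str, np.ndarray]
    training_meta: object = "pretrained"

    def __post_init__(self) -> None:
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has shape {vec.shape}, expected ({self.dim},)")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass(frozen=True)
class LabelVector:
    """Mean of the in-vocabulary constituent word vectors of one label."""

    source_id: str
    vector: Optional[np.ndarray]
    coverage: float

    @property
    def defined(self) -> bool:
        return self.vector is not None


def _corpus_fingerprint(corpus_tokens: Sequence[Sequence[str]]) -> str:
    h = hashlib.sha256()
    for doc in corpus_tokens:
        h.update(" ".join(doc).encode("utf-8"))
        h.update(b"\n")
    return h.hexdigest()[:16]


def train_embeddings(
    corpus_tokens: Sequence[Sequence[str]],
    dim: int,
    epochs: int = 100,
    window: int = 5,
    min_count: int = 1,
    rng_seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.025,
    min_learning_rate: float = 1e-4,
) -> EmbeddingTable:
    """Train skip-gram embeddings with negative sampling.

    Defaults mirror the reference configuration: 100 epochs, window 5,
    minimum count 1.  Context windows never cross document boundaries, the
    window size per position is drawn uniformly in [1, window], negatives are
    drawn from the unigram^0.75 distribution, and the learning rate decays
    linearly over all epochs.  Deterministic given ``rng_seed``.
    """
    if not corpus_tokens or all(len(d) == 0 for d in corpus_tokens):
        raise ValueError("corpus is empty")
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")

    freq = Counter(t for doc in corpus_tokens for t in doc)
    vocab = sorted(t for t, n in freq.items() if n >= min_count)
    if not vocab:
        raise ValueError(f"no token reaches min_count={min_count}")
    index = {t: k for k, t in enumerate(vocab)}
    docs = [np.array([index[t] for t in doc if t in index], dtype=np.int64) for doc in corpus_tokens]
    docs = [d for d in docs if len(d) > 0]

    rng = np.random.default_rng(rng_seed)
    v = len(vocab)
    w_in = (rng.random((v, dim)) - 0.5) / dim  # word2vec-style init
    w_out = np.zeros((v, dim))

    noise = np.array([freq[t] for t in vocab], dtype=np.float64) ** 0.75
    noise /= noise.sum()

    total_steps = max(1, epochs * sum(len(d) for d in docs))
    step = 0
    for _epoch in range(epochs):
        for doc in docs:
            n = len(doc)
            reduced = rng.integers(1, window + 1, size=n)
            for pos in range(n):
                lr = max(min_learning_rate, learning_rate * (1 - step / total_steps))
                step += 1
                b = int(reduced[pos])
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                center = doc[pos]
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    ctx = doc[ctx_pos]
                    # positive pair + k negatives, one SGD step each
                    targets = np.empty(negative + 1, dtype=np.int64)
                    targets[0] = ctx
                    targets[1:] = rng.choice(v, size=negative, p=noise)
                    labels = np.zeros(negative + 1)
                    labels[0] = 1.0
                    h = w_in[center]
                    z = w_out[targets] @ h
                    g = (labels - 1.0 / (1.0 + np.exp(-z))) * lr
                    grad_h = g @ w_out[targets]
                    np.add.at(w_out, targets, np.outer(g, h))
                    w_in[center] += grad_h

    meta = {
        "epochs": epochs,
        "window": window,
        "min_count": min_count,
        "dim": dim,
        "negative": negative,
        "learning_rate": learning_rate,
        "rng_seed": rng_seed,
        "corpus_fingerprint": _corpus_fingerprint(corpus_tokens),
    }
    return EmbeddingTable(dim=dim, vectors={t: w_in[index[t]].copy() for t in vocab}, training_meta=meta)


# ---------------------------------------------------------------------------
# Text-format I/O
# ---------------------------------------------------------------------------

def load_vectors(path, format: str = "word2vec_text") -> EmbeddingTable:
    """Load vectors from ``word2vec_text`` (header line) or ``glove_text``.

    Dimension is inferred from the first vector row and enforced on every
    subsequent row; duplicate tokens keep the first occurrence with a warning.
    """
    if format not in ("word2vec_text", "glove_text"):
        raise ValueError(f"unknown format {format!r}")
    vectors: Dict[str, np.ndarray] = {}
    dim: Optional[int] = None
    declared: Optional[tuple] = None
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(" ")
            if format == "word2vec_text" and ln == 1 and len(parts) == 2:
                try:
                    declared = (int(parts[0]), int(parts[1]))
                    continue
                except ValueError:
                    raise VectorFormatError(f"{path}:1: malformed word2vec header {line!r}")
            token, fields = parts[0], parts[1:]
            try:
                vec = np.array([float(x) for x in fields])
            except ValueError:
                raise VectorFormatError(f"{path}:{ln}: non-numeric vector field")
            if dim is None:
                if len(vec) < 1:
                    raise VectorFormatError(f"{path}:{ln}: empty vector row")
                dim = len(vec)
            elif len(vec) != dim:
                raise VectorFormatError(f"{path}:{ln}: expected {dim} values, got {len(vec)}")
            if token in vectors:
                warnings.warn(f"{path}:{ln}: duplicate token {token!r}, keeping first", stacklevel=2)
                continue
            vectors[token] = vec
    if dim is None:
        raise VectorFormatError(f"{path}: no vector rows")
    if declared is not None and declared[1] != dim:
        raise VectorFormatError(f"{path}: header declares dim {declared[1]}, rows have {dim}")
    return EmbeddingTable(dim=dim, vectors=vectors, training_meta="pretrained")


def write_vectors(table: EmbeddingTable, path, format: str = "word2vec_text", precision: int = 8) -> None:
    """Write the table in the given text dialect (tokens sorted, stable)."""
    if format not in ("word2vec_text", "glove_text"):
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if format == "word2vec_text":
            fh.write(f"{len(table.vectors)} {table.dim}\n")
        for token in sorted(table.vectors):
            vals = " ".join(f"{x:.{precision}g}" for x in table.vectors[token])
            fh.write(f"{token} {vals}\n")


# ---------------------------------------------------------------------------
# Label vectors
# ---------------------------------------------------------------------------

def label_vector(tokens, table: EmbeddingTable, source_id: Optional[str] = None) -> LabelVector:
    """Average the vectors of in-vocabulary tokens (multiset mean).

    ``tokens`` may be a TokenizedLabel or a plain token sequence.  OOV tokens
    are skipped; a label with no in-vocabulary token gets an undefined vector
    and coverage 0.
    """
    if hasattr(tokens, "tokens"):
        source_id = source_id if source_id is not None else tokens.source_id
        toks = list(tokens.tokens)
    else:
        toks = list(tokens)
        source_id = source_id if source_id is not None else ""
    in_vocab = [t for t in toks if t in table]
    coverage = len(in_vocab) / len(toks) if toks else 0.0
    if not in_vocab:
        return LabelVector(source_id=source_id, vector=None, coverage=0.0)
    vec = np.mean([table[t] for t in in_vocab], axis=0)
    return LabelVector(source_id=source_id, vector=vec, coverage=coverage)
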