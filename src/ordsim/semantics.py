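"""Semantic similarity matrices: measure combination and corpus-based LSA.

Expert-curated similarity matrices (e.g. averages of WordNet graph
measures) enter the pipeline as external labeled CSV inputs; this module
implements the combination step (optional per-measure min-max rescaling,
then element-wise averaging) and a small-corpus latent semantic analysis:
a weighted term-document matrix, truncated SVD with a factor cap, and
cosine similarity between scaled term vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import SimilarityMatrix, ValidationError, WordSet

__all__ = [
    "MeasureStack",
    "Corpus",
    "combine_measures",
    "lsa_term_similarity",
]


@dataclass(frozen=True)
class MeasureStack:
    """K similarity matrices from distinct measures over one WordSet."""

    words: WordSet
    measures: tuple[SimilarityMatrix, ...]
    names: tuple[str, ...]

    def __post_init__(self):
        if not self.measures:
            raise ValidationError("need at least one measure")
        if len(self.names) != len(self.measures):
            raise ValidationError("one name per measure")
        aligned = tuple(m.aligned_to(self.words) for m in self.measures)
        object.__setattr__(self, "measures", aligned)


@dataclass(frozen=True)
class Corpus:
    """Tokenized documents for LSA; one token list per document."""

    documents: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if len(self.documents) < 2:
            raise ValidationError("corpus needs at least 2 documents")

    @property
    def vocabulary(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for doc in self.documents:
            for tok in doc:
                seen.setdefault(tok, None)
        return tuple(seen)

    @classmethod
    def from_text(cls, text: str) -> "Corpus":
        """One document per line, whitespace-tokenized, lowercased."""
        docs = tuple(
            tuple(line.lower().split()) for line in text.splitlines() if line.strip()
        )
        return cls(docs)

    @classmethod
    def from_file(cls, path: str | Path) -> "Corpus":
        return cls.from_text(Path(path).read_text(encoding="utf-8"))


def combine_measures(stack: MeasureStack, normalization: str = "none") -> SimilarityMatrix:
    """Element-wise mean of the stacked measures.

    ``normalization="minmax"`` first rescales each measure to [0, 1] over
    all entries (diagonal included), removing scale differences between
    measures before averaging.
    """
    if normalization not in ("none", "minmax"):
        raise ValueError(f"normalization must be none|minmax, got {normalization!r}")
    mats = [m.sims.copy() for m in stack.measures]
    if normalization == "minmax":
        for i, m in enumerate(mats):
            lo, hi = m.min(), m.max()
            mats[i] = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
    return SimilarityMatrix(stack.words, np.mean(mats, axis=0))


def _log_entropy_weight(tf: np.ndarray) -> np.ndarray:
    """Log-entropy weighting of a terms x documents count matrix."""
    n_docs = tf.shape[1]
    gf = tf.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(gf > 0, tf / gf, 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    g = 1.0 + plogp.sum(axis=1) / np.log2(n_docs)
    return np.log2(1.0 + tf) * g[:, None]


def lsa_term_similarity(
    corpus: Corpus,
    words: WordSet,
    max_factors: int = 300,
    weighting: str = "log-entropy",
) -> SimilarityMatrix:
    """Latent-semantic-analysis similarity between the target words.

    Builds the weighted term-document matrix over the full corpus
    vocabulary, truncates the SVD to at most ``max_factors`` factors, and
    returns the cosine similarity between the scaled term vectors (term
    rows of U times the singular values).
    """
    if max_factors < 1:
        raise ValidationError("max_factors must be >= 1")
    if weighting not in ("log-entropy", "tf"):
        raise ValueError(f"weighting must be log-entropy|tf, got {weighting!r}")
    vocab = corpus.vocabulary
    vindex = {t: i for i, t in enumerate(vocab)}
    missing = [w for w in words if w.lower() not in vindex]
    if missing:
        raise ValidationError(f"words absent from corpus: {missing}")
    tf = np.zeros((len(vocab), len(corpus.documents)))
    for j, doc in enumerate(corpus.documents):
        for tok in doc:
            tf[vindex[tok], j] += 1.0
    weighted = _log_entropy_weight(tf) if weighting == "log-entropy" else tf
    u, s, _ = np.linalg.svd(weighted, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k = min(max_factors, rank)
    term_vecs = u[:, :k] * s[:k]
    rows = np.array([term_vecs[vindex[w.lower()]] for w in words])
    norms = np.linalg.norm(rows, axis=1)
    if (norms == 0).any():
        bad = [w for w, nn in zip(words, norms) if nn == 0]
        raise ValidationError(f"zero term vectors after truncation for: {bad}")
    sims = (rows @ rows.T) / np.outer(norms, norms)
    sims = np.clip(sims, -1.0, 1.0)
    return SimilarityMatrix(words, sims)
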