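"""Shared data types, label-aligned matrix I/O, configuration and logging.

All matrices in this package are square, indexed identically on rows and
columns by an ordered :class:`WordSet`.  Three kinds circulate: integer
confusion counts from a classification run, row-stochastic conditional
probability estimates derived from them, and real-valued semantic
similarities.  The downstream ordinal machinery consumes the latter two
interchangeably, row by row.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WordSet",
    "ConfusionMatrix",
    "CondProbMatrix",
    "SimilarityMatrix",
    "RunConfig",
    "ValidationError",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "row_normalize",
    "get_logger",
]

ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input file or matrix violates a structural invariant."""


def get_logger(name: str = "ordsim") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


@dataclass(frozen=True)
class WordSet:
    """Ordered, unique class labels shared by all matrices of one analysis.

    The label order is canonical: every matrix row/column index i refers to
    ``labels[i]`` everywhere in the package.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(w) for w in labels)
        if len(labels) < 2:
            raise ValidationError("a WordSet needs at least 2 labels")
        if len(set(labels)) != len(labels):
            dupes = sorted({w for w in labels if labels.count(w) > 1})
            raise ValidationError(f"duplicate labels: {dupes}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, word: str) -> int:
        try:
            return self.labels.index(word)
        except ValueError:
            raise KeyError(f"word {word!r} not in word set") from None

    def permutation_from(self, other: "WordSet") -> np.ndarray:
        """Index array p such that ``other.labels[p[i]] == self.labels[i]``.

        Label sets must match exactly; silent intersection would corrupt
        statistics that depend on N.
        """
        if set(other.labels) != set(self.labels):
            raise ValidationError(
                f"label sets differ: {sorted(set(self.labels) ^ set(other.labels))}"
            )
        pos = {w: i for i, w in enumerate(other.labels)}
        return np.array([pos[w] for w in self.labels], dtype=int)


def _as_square(values: np.ndarray, n: int, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != (n, n):
        raise ValidationError(f"{what}: expected {n}x{n} matrix, got {values.shape}")
    return values


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts; rows = true class, columns = predicted class."""

    words: WordSet
    counts: np.ndarray

    def __post_init__(self):
        counts = _as_square(self.counts, len(self.words), "confusion counts")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValidationError("confusion counts must be integers")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CondProbMatrix:
    """Row-stochastic conditional probability estimates p_ij."""

    words: WordSet
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(_as_square(self.probs, len(self.words), "probabilities"), float)
        if not np.isfinite(probs).all():
            raise ValidationError("probabilities must be finite")
        if (probs < -ROW_SUM_TOL).any() or (probs > 1 + ROW_SUM_TOL).any():
            raise ValidationError("probabilities must lie in [0, 1]")
        sums = probs.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            w = self.words.labels[bad[0]]
            raise ValidationError(
                f"row {w!r} sums to {sums[bad[0]]:.12g}, expected 1"
            )
        object.__setattr__(self, "probs", probs)

    def row(self, word: str) -> np.ndarray:
        return self.probs[self.words.index(word)]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Real-valued similarities; no symmetry requirement (rows are consumed
    independently by the ordinal machinery)."""

    words: WordSet
    sims: np.ndarray

    def __post_init__(self):
        sims = np.asarray(_as_square(self.sims, len(self.words), "similarities"), float)
        if not np.isfinite(sims).all():
            raise ValidationError("similarities must be finite")
        object.__setattr__(self, "sims", sims)

    def row(self, word: str) -> np.ndarray:
        return self.sims[self.words.index(word)]

    def aligned_to(self, words: WordSet) -> "SimilarityMatrix":
        """Permute rows and columns to another WordSet's canonical order."""
        p = words.permutation_from(self.words)
        return SimilarityMatrix(words, self.sims[np.ix_(p, p)])


@dataclass
class RunConfig:
    """Run-level knobs; the single integer seed feeds every random stage."""

    seed: int = 0
    folds: int = 5
    n_boot: int = 60
    alpha: float = 0.05
    rho_threshold_override: float | None = None
    tie_decimals: int | None = None

    def __post_init__(self):
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected flat key: value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )


# ---------------------------------------------------------------------------
# labeled-matrix CSV I/O


def _read_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValidationError(f"{path}: row labels do not match column labels")
    df.index = rows
    df.columns = cols
    return df


def read_labeled_matrix(
    path: str | Path, kind: str
) -> ConfusionMatrix | CondProbMatrix | SimilarityMatrix:
    """Read a labeled square CSV as one of the three matrix kinds.

    The CSV dialect is: comma-separated, UTF-8, header row of word labels
    with an empty first cell, first column of word labels.
    """
    if kind not in ("counts", "probs", "sims"):
        raise ValueError(f"kind must be counts|probs|sims, got {kind!r}")
    df = _read_frame(path)
    try:
        words = WordSet(df.index)
        values = df.to_numpy(float)
        if not np.isfinite(values).all():
            raise ValidationError(f"{path}: non-finite or non-numeric entries")
        if kind == "counts":
            return ConfusionMatrix(words, values)
        if kind == "probs":
            return CondProbMatrix(words, values)
        return SimilarityMatrix(words, values)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_labeled_matrix(
    mat: ConfusionMatrix | CondProbMatrix | SimilarityMatrix, path: str | Path
) -> None:
    """Write with repr-precision floats so a read round-trips losslessly."""
    if isinstance(mat, ConfusionMatrix):
        values: np.ndarray = mat.counts
        fmt = lambda v: str(int(v))  # noqa: E731
    else:
        values = mat.probs if isinstance(mat, CondProbMatrix) else mat.sims
        fmt = lambda v: repr(float(v))  # noqa: E731
    labels = mat.words.labels
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for w, row in zip(labels, values):
            fh.write(w + "," + ",".join(fmt(v) for v in row) + "\n")


def row_normalize(cm: ConfusionMatrix) -> CondProbMatrix:
    """Relative frequencies m_ij / sum_j m_ij, the conditional probability
    estimate that a sample of true class i is predicted as class j."""
    sums = cm.counts.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValidationError(
            f"word {cm.words.labels[zero[0]]!r} has no test samples (zero row)"
        )
    return CondProbMatrix(cm.words, cm.counts / sums[:, None])
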