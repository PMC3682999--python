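"""Rank correlation, exact permutation significance, and aggregation.

A per-word comparison is judged significant when the Spearman rank
correlation between the brain-derived row (conditional probabilities) and
the semantic row (model similarities) reaches the critical value of the
exact permutation null: the distribution of rho over all n! untied rank
permutations.  For n = 10 words the two-sided 0.05 critical value is
0.6485 (to four decimals).  The number of significant invariant partial
orders accumulated over bootstrap classification repetitions measures the
structural similarity between the decoding data and a semantic model.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import (
    CondProbMatrix,
    ConfusionMatrix,
    SimilarityMatrix,
    ValidationError,
    WordSet,
    row_normalize,
)
from .ordinal import (
    InvariantResult,
    build_connection_matrix,
    maximal_chains,
    maximal_common_subsequences,
)

__all__ = [
    "UnattainableAlpha",
    "SignificanceConfig",
    "WordAssessment",
    "StructuralSimilarityReport",
    "spearman_rho",
    "exact_rho_distribution",
    "exact_critical_rho",
    "assess_word",
    "count_significant",
    "Dendrogram",
    "cluster_tree",
]

EXACT_MAX_N = 10


class UnattainableAlpha(ValueError):
    """No attainable rho value has tail probability <= alpha/2."""


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman rank correlation.

    Average ranks are assigned to ties and rho is the Pearson correlation of
    the two rank vectors.  A constant row has no defined rank correlation;
    NaN is returned and treated downstream as not significant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_rho expects two equal-length vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(x, y).statistic
    return float(rho)


def _sum_d2_counts(n: int) -> dict[int, int]:
    """Exact counts of sum(d_i^2) over all n! untied rank permutations.

    Uses the identity sum d^2 = 2*sum(i^2) - 2*sum(i*perm(i)) and a
    subset-DP over the distribution of sum(i*perm(i)): processing positions
    1..n in order, the bitmask of used ranks determines the position index,
    so counts[mask] is a vector over partial sums.  O(2^n * n) vector ops.
    """
    max_t = sum(i * i for i in range(1, n + 1))
    counts = {0: np.zeros(max_t + 1, dtype=np.int64)}
    counts[0][0] = 1
    # iterate masks in increasing popcount via sorted order
    for mask in sorted(range(1 << n), key=lambda m: m.bit_count()):
        vec = counts.get(mask)
        if vec is None:
            continue
        k = mask.bit_count()  # next position is k+1
        if k == n:
            continue
        pos = k + 1
        for j in range(1, n + 1):
            bit = 1 << (j - 1)
            if mask & bit:
                continue
            new = mask | bit
            shift = pos * j
            tgt = counts.setdefault(new, np.zeros(max_t + 1, dtype=np.int64))
            tgt[shift:] += vec[: max_t + 1 - shift]
        del counts[mask]
    full = counts[(1 << n) - 1]
    sum_sq = n * (n + 1) * (2 * n + 1) // 6
    out: dict[int, int] = {}
    for t, c in enumerate(full):
        if c:
            out[2 * sum_sq - 2 * t] = int(c)
    return out


def exact_rho_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Attainable rho values (ascending) and their exact permutation counts."""
    if n < 3:
        raise ValidationError("exact null requires n >= 3")
    d2 = _sum_d2_counts(n)
    denom = n * (n * n - 1)
    items = sorted(d2.items(), reverse=True)  # largest d2 -> smallest rho
    rhos = np.array([1.0 - 6.0 * s / denom for s, _ in items])
    cnts = np.array([c for _, c in items], dtype=np.int64)
    return rhos, cnts


def exact_critical_rho(n: int, alpha: float = 0.05) -> float:
    """Critical rho of the exact two-sided permutation null.

    Enumerates the exact distribution of rho = 1 - 6*sum(d^2)/(n(n^2-1))
    over all n! untied rank permutations and returns the smallest attainable
    rho whose exact upper-tail probability is at most alpha/2.  For n above
    10 the enumeration is replaced by the t approximation, with a warning.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if n < 3:
        raise ValidationError("exact critical rho requires n >= 3")
    if n > EXACT_MAX_N:
        warnings.warn(
            f"n={n} > {EXACT_MAX_N}: using t approximation for critical rho",
            stacklevel=2,
        )
        t = sps.t.ppf(1 - alpha / 2, n - 2)
        return float(t / math.sqrt(n - 2 + t * t))
    rhos, cnts = exact_rho_distribution(n)
    total = math.factorial(n)
    upper_tail = np.cumsum(cnts[::-1])[::-1] / total  # P(rho >= rhos[i])
    ok = np.nonzero(upper_tail <= alpha / 2)[0]
    if ok.size == 0:
        raise UnattainableAlpha(
            f"no attainable rho has upper-tail probability <= {alpha / 2:g} at n={n}"
        )
    return float(rhos[ok[0]])


@dataclass
class SignificanceConfig:
    """Two-sided significance setup for per-word rho tests."""

    alpha: float = 0.05
    rho_threshold: float = None  # type: ignore[assignment]
    n: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.rho_threshold is None:
            if self.n is None:
                raise ValidationError(
                    "provide n to compute the exact threshold, or an override"
                )
            self.rho_threshold = exact_critical_rho(self.n, self.alpha)
        if not -1 <= self.rho_threshold <= 1:
            raise ValidationError("rho_threshold must lie in [-1, 1]")


@dataclass(frozen=True)
class WordAssessment:
    """Per-word outcome: correlation, significance flag, invariant chains."""

    focus_word: str
    rho: float
    significant: bool
    invariant: InvariantResult


@dataclass
class StructuralSimilarityReport:
    """Assessments for every (repetition, word) pair plus the headline count."""

    words: WordSet
    assessments: list[list[WordAssessment]]  # [repetition][word]
    total_significant: int
    max_possible: int

    def to_json(self) -> str:
        rows = []
        for rep, per_word in enumerate(self.assessments):
            for a in per_word:
                rows.append(
                    {
                        "repetition": rep,
                        "word": a.focus_word,
                        "rho": None if math.isnan(a.rho) else a.rho,
                        "significant": a.significant,
                        "max_length": a.invariant.max_length,
                        "invariant_chains": [list(c) for c in a.invariant.invariant_chains],
                    }
                )
        return json.dumps(
            {
                "total_significant": self.total_significant,
                "max_possible": self.max_possible,
                "assessments": rows,
            },
            indent=2,
        )


def assess_word(
    brain_row: Sequence[float],
    semantic_row: Sequence[float],
    focus: int,
    words: WordSet,
    cfg: SignificanceConfig,
    tie_decimals: int | None = None,
) -> WordAssessment:
    """Assess one focus word: build both orders, find the invariant chains,
    and test the rank correlation against the exact-null threshold."""
    order_b = build_connection_matrix(brain_row, focus, words, tie_decimals)
    order_p = build_connection_matrix(semantic_row, focus, words, tie_decimals)
    inv = maximal_common_subsequences(
        maximal_chains(order_b), maximal_chains(order_p), order_b, order_p
    )
    rho = spearman_rho(brain_row, semantic_row)
    significant = (not math.isnan(rho)) and rho >= cfg.rho_threshold
    return WordAssessment(words.labels[focus], rho, significant, inv)


def count_significant(
    cms: Sequence[ConfusionMatrix],
    sem: SimilarityMatrix,
    cfg: SignificanceConfig | None = None,
    tie_decimals: int | None = None,
) -> StructuralSimilarityReport:
    """Count significant invariant partial orders over classification
    repetitions.

    Each confusion matrix is row-normalized; for each word the brain row is
    compared with the semantic row; each (repetition, word) pair contributes
    at most one significant invariant order, so the maximum attainable count
    is n_repetitions * N.
    """
    if not cms:
        raise ValidationError("need at least one confusion matrix")
    words = cms[0].words
    sem = sem.aligned_to(words)
    if cfg is None:
        cfg = SignificanceConfig(n=len(words))
    assessments: list[list[WordAssessment]] = []
    total = 0
    for cm in cms:
        if cm.words.labels != words.labels:
            raise ValidationError("confusion matrices use different word sets")
        probs = row_normalize(cm).probs
        per_word = []
        for i in range(len(words)):
            a = assess_word(probs[i], sem.sims[i], i, words, cfg, tie_decimals)
            per_word.append(a)
            total += int(a.significant)
        assessments.append(per_word)
    return StructuralSimilarityReport(
        words=words,
        assessments=assessments,
        total_significant=total,
        max_possible=len(cms) * len(words),
    )


# ---------------------------------------------------------------------------
# complete-linkage similarity trees


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge table in scipy linkage format plus labels."""

    labels: tuple[str, ...]
    merges: np.ndarray  # (N-1, 4) scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            a, b, h, _ = self.merges[node - n]
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            return f"({render(a)}:{la:g},{render(b)}:{lb:g})"

        for k, row in enumerate(self.merges):
            height[n + k] = float(row[2])
        return render(2 * n - 2) + ";"


def cluster_tree(sim: SimilarityMatrix, distance: str = "smax") -> Dendrogram:
    """Complete (furthest) linkage agglomerative clustering of a similarity
    matrix.

    The matrix is symmetrized as (S + S.T)/2 and converted to distances with
    d = s_max - s (``smax``, s_max over off-diagonal entries) or d = 1 - s
    (``one-minus``, for similarities already in [0, 1]).  Ties between
    merge candidates are broken by smallest cluster index; heights are
    non-decreasing along the merge sequence.
    """
    n = len(sim.words)
    s = (sim.sims + sim.sims.T) / 2.0
    off = ~np.eye(n, dtype=bool)
    if distance == "smax":
        d = s[off].max() - s
    elif distance == "one-minus":
        d = 1.0 - s
    else:
        raise ValueError(f"unknown distance transform {distance!r}")
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    merges = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(labels=sim.words.labels, merges=merges)
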