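"""Synthetic recordings and confusion matrices with known ground truth.

The real recordings behind the geography-sentence experiments are not
publicly deposited, so every stage of the pipeline is exercised on
synthetic trials that emulate the experiment's statistical structure:
15 channels at an effective 62.5 Hz, per-word trial counts as used in the
experiment (640 trials for the first 10-word set), and per-word prototype
waveforms whose pairwise cosine similarities approximate a target semantic
similarity matrix.  Each trial is prototype-plus-Gaussian-noise; nothing
about real EEG spectra, artifacts or volume conduction is modelled — only
the structure the ordinal method consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CondProbMatrix,
    ConfusionMatrix,
    SimilarityMatrix,
    ValidationError,
    WordSet,
)
from .epochs import (
    DEFAULT_EXTENSION_SAMPLES,
    DEFAULT_OFFSET_SAMPLES,
    Event,
    Recording,
    TrialDataset,
)

__all__ = [
    "GeneratorSpec",
    "simulate_trials",
    "simulate_confusion",
    "geography_fixtures",
    "GeographyFixtures",
    "synthetic_semantic_matrix",
    "group_scrambled_decoy",
]

# Per-word trial frequencies of the geography-sentence experiment.
TRIAL_COUNTS: dict[str, int] = {
    "Berlin": 70, "London": 80, "Moscow": 90, "Paris": 80, "Rome": 80,
    "Warsaw": 80, "Madrid": 70, "Vienna": 40, "Athens": 50, "France": 40,
    "Germany": 40, "Italy": 40, "Poland": 40, "Russia": 50, "Austria": 40,
    "Greece": 40, "Spain": 50, "north": 60, "south": 70, "east": 60,
    "west": 70,
}

WORD_SETS: tuple[tuple[str, ...], ...] = (
    ("London", "Moscow", "Paris", "north", "south", "east", "west",
     "Germany", "Poland", "Russia"),
    ("Paris", "Vienna", "Athens", "north", "south", "east", "west",
     "Italy", "Spain", "Austria"),
    ("Berlin", "Rome", "Warsaw", "north", "south", "east", "west",
     "France", "Greece", "Poland"),
    ("Madrid", "Rome", "Vienna", "north", "south", "east", "west",
     "Spain", "Italy", "Austria"),
)

# Worked-example vectors for the focus word "London": combined-WordNet
# semantic similarities and decoding conditional probability estimates,
# on the first word set, in its canonical order.
_LONDON_LANGUAGE = {
    "London": 1.000, "Moscow": 0.396, "Paris": 0.466, "north": 0.106,
    "south": 0.103, "east": 0.076, "west": 0.078, "Germany": 0.322,
    "Poland": 0.299, "Russia": 0.303,
}
_LONDON_BRAIN = {
    "London": 0.275, "Moscow": 0.108, "Paris": 0.133, "north": 0.042,
    "south": 0.000, "east": 0.008, "west": 0.000, "Germany": 0.075,
    "Poland": 0.025, "Russia": 0.033,
}


@dataclass(frozen=True)
class GeographyFixtures:
    """Worked-example vectors, word sets and trial counts."""

    words: WordSet
    london_language: np.ndarray
    london_brain: np.ndarray
    word_sets: tuple[tuple[str, ...], ...]
    trial_counts: dict[str, int]


def geography_fixtures() -> GeographyFixtures:
    """In-package worked-example data for the first 10-word set."""
    words = WordSet(WORD_SETS[0])
    return GeographyFixtures(
        words=words,
        london_language=np.array([_LONDON_LANGUAGE[w] for w in words]),
        london_brain=np.array([_LONDON_BRAIN[w] for w in words]),
        word_sets=WORD_SETS,
        trial_counts=dict(TRIAL_COUNTS),
    )


def synthetic_semantic_matrix(
    words: WordSet | None = None, seed: int = 0, jitter: float = 0.03
) -> SimilarityMatrix:
    """Synthetic block-structured stand-in for an expert-curated semantic
    similarity matrix over the geography words.

    City names, country names and direction terms form within-group blocks
    (0.7) with weaker city-country coupling (0.4) and a cross-group floor
    (0.2); small seeded jitter breaks exact ties.  This is a synthetic
    construction, not data from any lexical database.
    """
    if words is None:
        words = WordSet(WORD_SETS[0])
    cities = {"Berlin", "London", "Moscow", "Paris", "Rome", "Warsaw",
              "Madrid", "Vienna", "Athens"}
    countries = {"France", "Germany", "Italy", "Poland", "Russia", "Austria",
                 "Greece", "Spain"}

    def group(w: str) -> str:
        if w in cities:
            return "city"
        if w in countries:
            return "country"
        return "direction"

    n = len(words)
    sims = np.full((n, n), 0.2)
    for i, wi in enumerate(words):
        for j, wj in enumerate(words):
            gi, gj = group(wi), group(wj)
            if gi == gj:
                sims[i, j] = 0.7
            elif {gi, gj} == {"city", "country"}:
                sims[i, j] = 0.4
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, jitter, size=(n, n))
    sims = sims + (noise + noise.T) / 2.0
    np.fill_diagonal(sims, 1.0)
    return SimilarityMatrix(words, sims)


def group_scrambled_decoy(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Relabel a geography-word similarity matrix so that semantic structure
    is destroyed, as a negative control.

    A single random permutation is a weak control for block-structured
    matrices: it tends to map whole groups (cities, countries, directions)
    onto each other, leaving most of the similarity structure intact.  The
    fixed derangement used here spreads every group's images across all
    three groups, so no pair of same-group words stays mutually similar
    (pigeonhole forces one residual pair inside the 4-word direction
    group).
    """
    perm = np.array([4, 7, 0, 1, 8, 3, 9, 2, 5, 6])
    if len(sim.words) != perm.size:
        raise ValidationError("decoy permutation is defined for 10-word sets")
    return SimilarityMatrix(sim.words, sim.sims[np.ix_(perm, perm)])


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions for one synthetic recording.

    Defaults mirror the experiment: the first 10-word set with its printed
    per-word trial counts (640 trials in total), 15 channels at 62.5 Hz,
    and a 70-sample epoch (a ~20-sample word plus the 50-sample
    extension).  ``snr`` is the prototype amplitude relative to unit
    Gaussian noise.
    """

    words: WordSet = field(default_factory=lambda: WordSet(WORD_SETS[0]))
    trials_per_word: tuple[int, ...] | None = None
    channels: int = 15
    rate_hz: float = 62.5
    epoch_len: int = 70
    snr: float = 1.0
    target_sim: SimilarityMatrix | None = None
    seed: int = 0

    def resolved_trials(self) -> tuple[int, ...]:
        if self.trials_per_word is not None:
            trials = tuple(int(t) for t in self.trials_per_word)
            if len(trials) != len(self.words) or any(t <= 0 for t in trials):
                raise ValidationError("trials_per_word must be positive, one per word")
            return trials
        return tuple(TRIAL_COUNTS.get(w, 50) for w in self.words)

    def resolved_target(self) -> SimilarityMatrix:
        if self.target_sim is not None:
            return self.target_sim.aligned_to(self.words)
        return synthetic_semantic_matrix(self.words, seed=self.seed)


def _prototypes(target: SimilarityMatrix, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Per-word prototype vectors whose Gram matrix approximates the
    min-max-scaled target similarities (PSD projection by eigenvalue
    clipping), embedded in the feature space by a seeded orthonormal basis.
    """
    s = np.asarray(target.sims, float)
    lo, hi = s.min(), s.max()
    scaled = (s - lo) / (hi - lo) if hi > lo else np.ones_like(s)
    scaled = (scaled + scaled.T) / 2.0
    eigval, eigvec = np.linalg.eigh(scaled)
    clipped = (eigval < -1e-8).any()
    if clipped:
        warnings.warn(
            "target similarity matrix is not positive semi-definite; "
            "negative eigenvalues clipped at 0",
            stacklevel=3,
        )
    eigval = np.clip(eigval, 0.0, None)
    factors = eigvec * np.sqrt(eigval)  # N x N, rows have Gram ~= scaled
    n = factors.shape[0]
    if dim < n:
        raise ValidationError(f"feature dim {dim} smaller than word count {n}")
    basis, _ = np.linalg.qr(rng.standard_normal((dim, n)))
    protos = factors @ basis.T  # N x dim
    # unit-RMS scale so snr is amplitude per channel-sample
    rms = np.sqrt(np.mean(protos**2))
    if rms > 0:
        protos /= rms
    return protos


def simulate_trials(spec: GeneratorSpec) -> tuple[Recording, TrialDataset]:
    """Generate a recording plus its ground-truth trial dataset.

    Each trial is ``snr * prototype + unit Gaussian noise`` per
    channel-sample, laid into a continuous noise background at randomized
    trial order; the emitted events table has durations of
    ``epoch_len - 50`` samples so standard epoch extraction recovers
    exactly the planted windows.  Pure function of the spec's seed.
    """
    if spec.snr < 0:
        raise ValidationError("snr must be >= 0")
    if spec.epoch_len <= DEFAULT_EXTENSION_SAMPLES:
        raise ValidationError(
            f"epoch_len must exceed the {DEFAULT_EXTENSION_SAMPLES}-sample extension"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    words = spec.words
    trials = spec.resolved_trials()
    target = spec.resolved_target()
    dim = spec.channels * spec.epoch_len
    protos = _prototypes(target, dim, rng)

    labels = np.repeat(np.arange(len(words)), trials)
    rng.shuffle(labels)
    t_total = labels.size
    slot = DEFAULT_OFFSET_SAMPLES + spec.epoch_len + 5  # onset gap + epoch + pad
    n_time = t_total * slot + slot
    signal = rng.standard_normal((spec.channels, n_time))

    duration = spec.epoch_len - DEFAULT_EXTENSION_SAMPLES
    feats = np.empty((t_total, dim))
    events = []
    for t, lab in enumerate(labels):
        onset = t * slot
        epoch = spec.snr * protos[lab] + rng.standard_normal(dim)
        feats[t] = epoch
        start = onset + DEFAULT_OFFSET_SAMPLES
        signal[:, start : start + spec.epoch_len] = epoch.reshape(
            spec.channels, spec.epoch_len
        )
        events.append(Event(words.labels[lab], onset, onset + duration, t))
    rec = Recording(signal, spec.rate_hz, tuple(events))
    ds = TrialDataset(words, feats, labels)
    return rec, ds


def simulate_confusion(
    p_target: CondProbMatrix, row_counts: list[int] | tuple[int, ...], seed: int
) -> ConfusionMatrix:
    """Draw each confusion row multinomially from a target conditional
    probability row; pure function of the seed."""
    n = len(p_target.words)
    counts = np.asarray(row_counts, int)
    if counts.shape != (n,) or (counts <= 0).any():
        raise ValidationError("row_counts must be positive, one per word")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.vstack(
        [rng.multinomial(counts[i], p_target.probs[i]) for i in range(n)]
    )
    return ConfusionMatrix(p_target.words, out)
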