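"""Epoch extraction and cross-validated linear-discriminant classification.

Word-locked epochs are cut from a multichannel recording, concatenated
across channels into equal-length feature vectors, and classified with a
linear discriminant in a stratified cross-validation loop after per-fold
principal-component reduction.  The accumulated true-vs-predicted counts
form the confusion matrix the ordinal machinery consumes.  The classifier
is a documented stand-in that preserves the structure of the original
decoding pipeline (linear discriminant, nested PCA, 5-fold CV); the
downstream method is classifier-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core import ConfusionMatrix, CondProbMatrix, ValidationError, WordSet, row_normalize

__all__ = [
    "Event",
    "Recording",
    "TrialDataset",
    "ClassifierSpec",
    "extract_epochs",
    "classify_cv",
    "bootstrap_classify",
    "cumulative_condprob",
    "read_recording",
]

DEFAULT_OFFSET_SAMPLES = 10  # 160 ms at 62.5 Hz
DEFAULT_EXTENSION_SAMPLES = 50  # ~800 ms at 62.5 Hz


@dataclass(frozen=True)
class Event:
    word: str
    onset: int
    offset: int
    trial: int


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel signal with a word-event table."""

    signal: np.ndarray  # channels x time
    rate_hz: float
    events: tuple[Event, ...]

    def __post_init__(self):
        signal = np.asarray(self.signal, float)
        if signal.ndim != 2 or signal.shape[0] < 1:
            raise ValidationError("signal must be a channels x time matrix")
        for ev in self.events:
            if not 0 <= ev.onset < ev.offset <= signal.shape[1]:
                raise ValidationError(
                    f"event {ev.trial} ({ev.word!r}): onset/offset outside signal"
                )
        object.__setattr__(self, "signal", signal)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


@dataclass(frozen=True)
class TrialDataset:
    """Equal-length feature vectors (channel epochs concatenated) and their
    word labels."""

    words: WordSet
    features: np.ndarray  # T x (channels * L)
    labels: np.ndarray  # T word indices

    def __post_init__(self):
        feats = np.asarray(self.features, float)
        labels = np.asarray(self.labels, int)
        if feats.ndim != 2 or feats.shape[0] != labels.shape[0]:
            raise ValidationError("features and labels disagree on trial count")
        present = set(labels.tolist())
        missing = [w for i, w in enumerate(self.words.labels) if i not in present]
        if missing:
            raise ValidationError(f"words with no trials: {missing}")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)

    @property
    def n_trials(self) -> int:
        return int(self.labels.shape[0])


@dataclass(frozen=True)
class ClassifierSpec:
    """Stand-in decoding pipeline: stratified k-fold CV, per-fold PCA by
    retained-variance fraction, linear discriminant with shrinkage-regularized
    pooled covariance (``shrinkage=None`` selects Ledoit-Wolf automatically).
    """

    folds: int = 5
    pca_variance: float = 0.95
    shrinkage: float | None = None

    def __post_init__(self):
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if not 0 < self.pca_variance <= 1:
            raise ValidationError("pca_variance must be in (0, 1]")
        if self.shrinkage is not None and not 0 <= self.shrinkage <= 1:
            raise ValidationError("shrinkage must be in [0, 1]")


def extract_epochs(
    rec: Recording,
    offset_samples: int = DEFAULT_OFFSET_SAMPLES,
    extension_samples: int = DEFAULT_EXTENSION_SAMPLES,
) -> TrialDataset:
    """Cut equal-length word epochs from a recording.

    Each event contributes its duration plus ``extension_samples``; the
    common epoch length L is the floor of the mean over all events.  Each
    sample spans ``[onset + offset_samples, onset + offset_samples + L)`` on
    every channel, channels concatenated in channel order.  At 62.5 Hz the
    default 10-sample onset offset is 160 ms and the 50-sample extension is
    about 800 ms.
    """
    if not rec.events:
        raise ValidationError("recording has no events")
    lengths = [(ev.offset - ev.onset) + extension_samples for ev in rec.events]
    L = int(np.floor(np.mean(lengths)))
    if L <= 0:
        raise ValidationError(f"computed epoch length {L} <= 0")
    n_time = rec.signal.shape[1]
    overruns = [
        ev for ev in rec.events if ev.onset + offset_samples + L > n_time
    ]
    if overruns:
        ev = overruns[0]
        raise ValidationError(
            f"epoch for event trial={ev.trial} word={ev.word!r} extends past the "
            f"end of the signal ({ev.onset + offset_samples + L} > {n_time}); "
            f"{len(overruns)} event(s) affected"
        )
    words = WordSet(dict.fromkeys(ev.word for ev in rec.events))
    feats = np.empty((len(rec.events), rec.n_channels * L))
    labels = np.empty(len(rec.events), dtype=int)
    for t, ev in enumerate(rec.events):
        start = ev.onset + offset_samples
        feats[t] = rec.signal[:, start : start + L].reshape(-1)
        labels[t] = words.index(ev.word)
    return TrialDataset(words, feats, labels)


def _fit_predict_fold(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    spec: ClassifierSpec,
) -> np.ndarray:
    mean = train_x.mean(axis=0)
    xc = train_x - mean
    max_rank = min(xc.shape[0] - 1, xc.shape[1])
    if spec.pca_variance >= 1.0:
        pca = PCA(n_components=max_rank, svd_solver="full")
    else:
        pca = PCA(n_components=spec.pca_variance, svd_solver="full")
    z_train = pca.fit_transform(xc)
    z_test = pca.transform(test_x - mean)
    shrink = "auto" if spec.shrinkage is None else spec.shrinkage
    # uniform priors: with unequal per-word trial counts, empirical priors
    # would push misclassifications toward frequent words and leak base
    # rates into the confusion structure the ordinal analysis consumes
    classes = np.unique(train_y)
    lda = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage=shrink, priors=np.full(classes.size, 1 / classes.size)
    )
    lda.fit(z_train, train_y)
    return lda.predict(z_test)


def classify_cv(
    ds: TrialDataset, spec: ClassifierSpec, seed: int
) -> ConfusionMatrix:
    """Stratified k-fold cross-validated classification.

    Fold assignment is a deterministic function of (seed, labels); counts
    accumulate true-vs-predicted over all folds, so they sum to the number
    of trials.
    """
    n = len(ds.words)
    counts = np.bincount(ds.labels, minlength=n)
    small = np.nonzero(counts < spec.folds)[0]
    if small.size:
        raise ValidationError(
            f"class {ds.words.labels[small[0]]!r} has {counts[small[0]]} samples, "
            f"fewer than {spec.folds} folds"
        )
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=seed % (2**32))
    conf = np.zeros((n, n), dtype=np.int64)
    for train_idx, test_idx in skf.split(ds.features, ds.labels):
        pred = _fit_predict_fold(
            ds.features[train_idx], ds.labels[train_idx], ds.features[test_idx], spec
        )
        np.add.at(conf, (ds.labels[test_idx], pred), 1)
    return ConfusionMatrix(ds.words, conf)


def bootstrap_classify(
    ds: TrialDataset,
    spec: ClassifierSpec,
    n_boot: int,
    seed: int,
    resample: bool = True,
) -> list[ConfusionMatrix]:
    """Repeated single-trial classification with within-class resampling.

    Each repetition resamples trials with replacement within each class
    (class counts preserved, so every word stays estimable in every
    repetition) and reruns the cross-validated classification with a fresh
    fold seed.  With ``resample=False`` and ``n_boot=1`` this is exactly
    ``classify_cv``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_boot)
    out = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if resample:
            idx = []
            for cls in range(len(ds.words)):
                members = np.nonzero(ds.labels == cls)[0]
                idx.append(rng.choice(members, size=members.size, replace=True))
            idx = np.concatenate(idx)
            boot = TrialDataset(ds.words, ds.features[idx], ds.labels[idx])
        else:
            boot = ds
        # single no-resample repetition is exactly classify_cv at `seed`;
        # otherwise each repetition gets a fresh fold seed
        use_seed = seed if (not resample and n_boot == 1) else fold_seed
        out.append(classify_cv(boot, spec, use_seed))
    return out


def cumulative_condprob(cms: Sequence[ConfusionMatrix]) -> list[CondProbMatrix]:
    """Cumulative averages of the conditional probability estimates.

    Element k is the element-wise mean of the row-normalized first k
    matrices; each mean of row-stochastic matrices is row-stochastic.
    """
    if not cms:
        raise ValidationError("need at least one confusion matrix")
    words = cms[0].words
    acc = np.zeros((len(words), len(words)))
    out = []
    for k, cm in enumerate(cms, start=1):
        if cm.words.labels != words.labels:
            raise ValidationError("confusion matrices use different word sets")
        acc += row_normalize(cm).probs
        out.append(CondProbMatrix(words, acc / k))
    return out


def read_recording(signal_path: str | Path, events_path: str | Path, rate_hz: float = 62.5) -> Recording:
    """Read a recording from a delimited channels x time file plus a TSV
    events table with columns trial, word, onset_sample, offset_sample."""
    signal = np.loadtxt(signal_path, delimiter=",")
    if signal.ndim == 1:
        signal = signal[None, :]
    ev = pd.read_csv(events_path, sep="\t")
    required = {"trial", "word", "onset_sample", "offset_sample"}
    missing = required - set(ev.columns)
    if missing:
        raise ValidationError(f"{events_path}: missing columns {sorted(missing)}")
    events = tuple(
        Event(str(r.word), int(r.onset_sample), int(r.offset_sample), int(r.trial))
        for r in ev.itertuples()
    )
    return Recording(signal, rate_hz, events)


def write_recording(rec: Recording, signal_path: str | Path, events_path: str | Path) -> None:
    np.savetxt(signal_path, rec.signal, delimiter=",")
    rows = [
        {"trial": ev.trial, "word": ev.word, "onset_sample": ev.onset, "offset_sample": ev.offset}
        for ev in rec.events
    ]
    pd.DataFrame(rows).to_csv(events_path, sep="\t", index=False)
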