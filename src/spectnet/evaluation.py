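"""Leave-pair-out evaluation of frame classifiers at the subject level.

The experiment loop, repeated N times:

1. hold out one random subject per class (the test pair);
2. balance the remaining training subjects by random replication of the
   smaller class, so both classes contribute equally many subject slots
   (and hence frames);
3. fit the frame normalization on the training frames, train the frame
   classifier by stochastic gradient descent;
4. score frames on train and test sets;
5. score subjects by averaging their frames' class-probability vectors
   and taking the maximal-probability class (a 0.5 threshold in the
   binary case; exact ties resolve to the first class index).

Aggregation reports mean, SD and standard error of the mean of each metric
over the N experiments, plus the Wilcoxon-Mann-Whitney AUC computed on the
held-out subject scores pooled across folds (a per-fold AUC on a single
pair would be degenerate).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FrameSet
from .spectrogram import FrameNormalizer

__all__ = ["LPOSplit", "SubjectScore", "FoldResult", "EvaluationSummary",
           "make_lpo_split", "balance_by_replication", "score_subject",
           "wmw_auc", "run_experiments", "channel_sweep",
           "permute_subject_labels"]


@dataclass
class LPOSplit:
    """One leave-pair-out split: a test subject per class plus a balanced
    training multiset (replicated ids appear multiple times)."""

    test_pair: dict[str, str]          # class label -> held-out subject
    train_subjects: list[str]          # balanced multiset of subject ids

    def __post_init__(self):
        overlap = set(self.test_pair.values()) & set(self.train_subjects)
        if overlap:
            raise ValueError(f"test subjects leak into training: {overlap}")


@dataclass
class SubjectScore:
    subject_id: str
    probabilities: np.ndarray          # mean over the subject's frames
    predicted_label: str
    true_label: str

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


@dataclass
class FoldResult:
    split: LPOSplit
    train_frame_accuracy: float
    test_frame_accuracy: float
    subject_scores: list[SubjectScore]

    @property
    def subject_accuracy(self) -> float:
        return float(np.mean([s.correct for s in self.subject_scores]))


@dataclass
class EvaluationSummary:
    """Mean +/- SD (and SEM) over N experiments, plus pooled-score AUC."""

    n_experiments: int
    train_frame_accuracy: tuple[float, float]
    test_frame_accuracy: tuple[float, float]
    subject_accuracy: tuple[float, float]
    auc: float
    folds: list[FoldResult] = field(default_factory=list)

    @staticmethod
    def _sem(sd: float, n: int) -> float:
        return sd / np.sqrt(n) if n > 0 else float("nan")

    @property
    def subject_accuracy_sem(self) -> float:
        return self._sem(self.subject_accuracy[1], self.n_experiments)

    @property
    def test_frame_accuracy_sem(self) -> float:
        return self._sem(self.test_frame_accuracy[1], self.n_experiments)

    def to_dict(self) -> dict:
        return {
            "n_experiments": self.n_experiments,
            "train_frame_accuracy_mean": self.train_frame_accuracy[0],
            "train_frame_accuracy_sd": self.train_frame_accuracy[1],
            "test_frame_accuracy_mean": self.test_frame_accuracy[0],
            "test_frame_accuracy_sd": self.test_frame_accuracy[1],
            "test_frame_accuracy_sem": self.test_frame_accuracy_sem,
            "subject_accuracy_mean": self.subject_accuracy[0],
            "subject_accuracy_sd": self.subject_accuracy[1],
            "subject_accuracy_sem": self.subject_accuracy_sem,
            "auc": self.auc,
        }

    def folds_frame(self) -> pd.DataFrame:
        rows = []
        for k, f in enumerate(self.folds):
            row = {"fold": k,
                   "train_frame_accuracy": f.train_frame_accuracy,
                   "test_frame_accuracy": f.test_frame_accuracy,
                   "subject_accuracy": f.subject_accuracy}
            for s in f.subject_scores:
                row[f"score[{s.true_label}]"] = float(
                    s.probabilities.max())
                row[f"subject[{s.true_label}]"] = s.subject_id
            rows.append(row)
        return pd.DataFrame(rows)


def make_lpo_split(subject_labels: dict[str, str],
                   rng: np.random.Generator | int | None = None) -> LPOSplit:
    """Hold out one random subject per class; balance the rest by random
    replication (with replacement) of the smaller classes."""
    rng = np.random.default_rng(rng)
    by_class: dict[str, list[str]] = {}
    for sid in sorted(subject_labels):
        by_class.setdefault(subject_labels[sid], []).append(sid)
    for label, sids in by_class.items():
        if len(sids) < 2:
            raise ValueError(
                f"class {label!r} has {len(sids)} subject(s); need >= 2 to "
                "hold one out and still train")
    test_pair = {label: sids[rng.integers(len(sids))]
                 for label, sids in sorted(by_class.items())}
    remaining = {label: [s for s in sids if s != test_pair[label]]
                 for label, sids in sorted(by_class.items())}
    target = max(len(v) for v in remaining.values())
    train: list[str] = []
    for label in sorted(remaining):
        sids = remaining[label]
        train.extend(sids)
        deficit = target - len(sids)
        if deficit > 0:
            train.extend(str(sids[i])
                         for i in rng.integers(len(sids), size=deficit))
    return LPOSplit(test_pair=test_pair, train_subjects=train)


def balance_by_replication(frameset: FrameSet, split: LPOSplit
                           ) -> tuple[FrameSet, FrameSet]:
    """Materialize (train, test) framesets for a split; replicated train
    subjects contribute their frames once per replication slot."""
    train = frameset.select_subjects(split.train_subjects)
    test = frameset.select_subjects(sorted(split.test_pair.values()))
    return train, test


def score_subject(frame_probs: np.ndarray, subject_id: str = "",
                  true_label: str = "",
                  class_names: list[str] | None = None) -> SubjectScore:
    """Average a subject's frame probability rows into a subject score.

    The predicted label is the maximal-probability class; an exact tie
    resolves to the first class index.
    """
    frame_probs = np.atleast_2d(np.asarray(frame_probs, dtype=float))
    if frame_probs.shape[0] == 0:
        raise ValueError("subject has no frames to score")
    mean = frame_probs.mean(axis=0)
    idx = int(np.argmax(mean))
    if class_names is None:
        class_names = [str(i) for i in range(len(mean))]
    return SubjectScore(subject_id=subject_id, probabilities=mean,
                        predicted_label=class_names[idx],
                        true_label=true_label)


def wmw_auc(scores_class1, scores_class0) -> float:
    """Wilcoxon-Mann-Whitney AUC.

    The probability that a random class-1 score exceeds a random class-0
    score, counting exact ties as 1/2:
    AUC = [#(s1 > s0) + 0.5 #(s1 = s0)] / (n1 * n0).
    """
    s1 = np.asarray(scores_class1, dtype=float)
    s0 = np.asarray(scores_class0, dtype=float)
    if s1.size == 0 or s0.size == 0:
        raise ValueError("both score lists must be non-empty")
    diff = s1[:, None] - s0[None, :]
    return float((np.count_nonzero(diff > 0)
                  + 0.5 * np.count_nonzero(diff == 0)) / (s1.size * s0.size))


def _frame_accuracy(model, frames: FrameSet, class_names: list[str]
                    ) -> float:
    proba = model.predict_proba(frames.frames)
    pred = proba.argmax(axis=1)
    truth = frames.label_array(class_names)
    return float(np.mean(pred == truth))


def evaluate_fold(frameset: FrameSet, model, split: LPOSplit, *,
                  normalizer: FrameNormalizer | None = None) -> FoldResult:
    """Train the (unfitted) ``model`` on a split's balanced training
    frames, with normalization fitted on those frames only, and score the
    held-out pair."""
    class_names = frameset.class_names
    train_fs, test_fs = balance_by_replication(frameset, split)
    norm = normalizer if normalizer is not None else FrameNormalizer()
    norm.fit(train_fs.frames)
    xtr = norm.transform(train_fs.frames)
    xte = norm.transform(test_fs.frames)
    train_norm = FrameSet(xtr, train_fs.subject_ids, train_fs.labels,
                          train_fs.freq_axis, train_fs.channel_labels)
    # labels enter training as integer indices in sorted class-name order,
    # so probability columns align with class_names
    model.fit(train_norm.frames, train_norm.label_array(class_names))
    train_acc = _frame_accuracy(model, train_norm, class_names)
    test_norm = FrameSet(xte, test_fs.subject_ids, test_fs.labels,
                         test_fs.freq_axis, test_fs.channel_labels)
    test_acc = _frame_accuracy(model, test_norm, class_names)
    scores = []
    for label in sorted(split.test_pair):
        sid = split.test_pair[label]
        probs = model.predict_proba(test_norm.frames_for_subject(sid))
        scores.append(score_subject(probs, sid, label, class_names))
    return FoldResult(split=split, train_frame_accuracy=train_acc,
                      test_frame_accuracy=test_acc, subject_scores=scores)


def pooled_auc(folds: list[FoldResult], class_names: list[str]) -> float:
    """Pooled-score AUC with class_names[-1] as the positive class; the
    score is that class's mean frame probability per subject."""
    col = len(class_names) - 1
    positive = class_names[col]
    pos = [s.probabilities[col] for f in folds for s in f.subject_scores
           if s.true_label == positive]
    neg = [s.probabilities[col] for f in folds for s in f.subject_scores
           if s.true_label != positive]
    return wmw_auc(pos, neg)


def run_experiments(frameset: FrameSet, model_builder, n_experiments: int,
                    rng_seed: int | np.random.Generator = 0
                    ) -> EvaluationSummary:
    """The repeated leave-pair-out loop.

    ``model_builder(seed)`` returns a fresh unfitted estimator per fold;
    the per-fold seed is derived from ``rng_seed`` so the whole run is
    reproducible.
    """
    rng = np.random.default_rng(rng_seed)
    labels = frameset.subject_labels()
    class_names = frameset.class_names
    folds: list[FoldResult] = []
    for k in range(n_experiments):
        split = make_lpo_split(labels, rng)
        seed = int(rng.integers(0, 2 ** 31))
        try:
            folds.append(evaluate_fold(frameset, model_builder(seed), split))
        except Exception as err:
            raise RuntimeError(f"fold {k} failed: {err}") from err
    def ms(vals):
        a = np.asarray(vals, dtype=float)
        return float(a.mean()), float(a.std(ddof=0))
    return EvaluationSummary(
        n_experiments=n_experiments,
        train_frame_accuracy=ms([f.train_frame_accuracy for f in folds]),
        test_frame_accuracy=ms([f.test_frame_accuracy for f in folds]),
        subject_accuracy=ms([f.subject_accuracy for f in folds]),
        auc=pooled_auc(folds, class_names),
        folds=folds)


def channel_sweep(frameset: FrameSet, channels, model_builder,
                  n_experiments_per_channel: int,
                  rng_seed: int = 0) -> pd.DataFrame:
    """Single-channel performance map: run the experiment loop per channel.

    Each channel gets an independent seed derived from ``rng_seed`` and its
    own position-independent stream, so results do not depend on sweep
    order. Returns a table sortable by AUC.
    """
    rows = []
    for ch in channels:
        if isinstance(ch, str) and ch not in frameset.channel_labels:
            raise KeyError(f"unknown channel label {ch!r}")
        sub = frameset.select_channels([ch])
        label = ch if isinstance(ch, str) else frameset.channel_labels[ch]
        # per-channel stream keyed by a stable label digest: results are
        # independent of sweep order and reproducible across processes
        digest = zlib.crc32(label.encode()) % (2 ** 31)
        child_seed = int(np.random.default_rng(
            [rng_seed, digest]).integers(0, 2 ** 31))
        summary = run_experiments(sub, model_builder,
                                  n_experiments_per_channel, child_seed)
        row = {"channel": label, **summary.to_dict()}
        rows.append(row)
    return pd.DataFrame(rows)


def permute_subject_labels(frameset: FrameSet,
                           rng: np.random.Generator | int | None = None
                           ) -> FrameSet:
    """Randomly reassign class labels across subjects (label counts
    preserved) — the permutation null for chance-level checks."""
    rng = np.random.default_rng(rng)
    subjects = frameset.subjects
    labels = [frameset.subject_label(s) for s in subjects]
    perm = rng.permutation(len(labels))
    mapping = {s: labels[perm[i]] for i, s in enumerate(subjects)}
    new_labels = np.array([mapping[s] for s in frameset.subject_ids],
                          dtype=object)
    return FrameSet(frameset.frames, frameset.subject_ids, new_labels,
                    frameset.freq_axis, frameset.channel_labels)
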