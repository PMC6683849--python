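"""Core data containers: recordings, spectrogram frames, frame sets.

The frame is the classifier's input unit: a (channels, frequency bins,
time epochs) amplitude array covering 20 s of EEG on a 4-44 Hz grid at
2 Hz spacing (21 bins x 20 one-second epochs by default). A FrameSet
groups labeled frames by subject, which is what subject-aware splitting
and subject-level scoring operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Analysis band retained from each epoch spectrum, inclusive (Hz).
FREQ_MIN = 4.0
FREQ_MAX = 44.0
#: Spacing of the aggregated frequency bins (Hz).
FREQ_STEP = 2.0
#: Number of frequency bins: 4, 6, ..., 44 Hz.
N_FREQ_BINS = 21
#: One-second epochs per frame (frame length in s).
FRAME_EPOCHS = 20
#: Frames retained per subject (~2.5 min of data at 1-s stride).
FRAMES_PER_SUBJECT = 148


def default_freq_axis() -> np.ndarray:
    """Center frequencies of the aggregated bins: 4, 6, ..., 44 Hz."""
    return np.arange(FREQ_MIN, FREQ_MAX + FREQ_STEP / 2, FREQ_STEP)


@dataclass
class EEGRecording:
    """Multichannel EEG time series with subject metadata.

    data is (channels, samples) in arbitrary amplitude units (uV for real
    EEG); channel_labels follow the 10-20 convention for real recordings.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    subject_id: str
    class_label: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.sampling_rate


@dataclass
class SpectrogramFrame:
    """One (channels, freq bins, epochs) amplitude frame."""

    values: np.ndarray
    freq_axis: np.ndarray = field(default_factory=default_freq_axis)
    start_time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (channels, freq_bins, epochs)")
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        if self.freq_axis.shape[0] != self.values.shape[1]:
            raise ValueError("freq_axis length must match frequency axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


class FrameSet:
    """Labeled frames grouped by subject.

    Stores frames densely as a (n_frames, channels, freq_bins, epochs)
    array with per-frame subject ids and class labels; class labels are
    constant within a subject (validated).
    """

    def __init__(self, frames: np.ndarray, subject_ids, labels,
                 freq_axis: np.ndarray | None = None,
                 channel_labels: list[str] | None = None):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 4:
            raise ValueError(
                "frames must be (n, channels, freq_bins, epochs)")
        subject_ids = np.asarray(subject_ids, dtype=object)
        labels = np.asarray(labels, dtype=object)
        if not (len(subject_ids) == len(labels) == frames.shape[0]):
            raise ValueError("frames, subject_ids, labels must align")
        for sid in np.unique(subject_ids):
            lab = labels[subject_ids == sid]
            if len(set(lab)) != 1:
                raise ValueError(
                    f"subject {sid!r} carries more than one class label")
        self.frames = frames
        self.subject_ids = subject_ids
        self.labels = labels
        self.freq_axis = (np.asarray(freq_axis, dtype=float)
                          if freq_axis is not None else default_freq_axis())
        if channel_labels is None:
            channel_labels = [f"ch{i}" for i in range(frames.shape[1])]
        if len(channel_labels) != frames.shape[1]:
            raise ValueError("channel_labels must match channel count")
        self.channel_labels = list(channel_labels)

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.subject_ids:
            seen.setdefault(sid, None)
        return list(seen)

    @property
    def class_names(self) -> list[str]:
        return sorted(set(self.labels))

    def subject_label(self, subject_id: str) -> str:
        mask = self.subject_ids == subject_id
        if not mask.any():
            raise KeyError(f"unknown subject {subject_id!r}")
        return self.labels[mask][0]

    def subject_labels(self) -> dict[str, str]:
        return {sid: self.subject_label(sid) for sid in self.subjects}

    # -- subsetting ----------------------------------------------------------

    def subset_frames(self, index: np.ndarray) -> "FrameSet":
        return FrameSet(self.frames[index], self.subject_ids[index],
                        self.labels[index], self.freq_axis,
                        self.channel_labels)

    def frames_for_subject(self, subject_id: str) -> np.ndarray:
        return self.frames[self.subject_ids == subject_id]

    def select_subjects(self, subject_ids, replicate: bool = True
                        ) -> "FrameSet":
        """Frames of the given subjects, in the given order.

        Duplicated ids contribute their frames once per occurrence, which is
        how class balancing by subject replication enters the training set.
        """
        blocks, sids, labs = [], [], []
        for k, sid in enumerate(subject_ids):
            f = self.frames_for_subject(sid)
            if f.shape[0] == 0:
                raise KeyError(f"unknown subject {sid!r}")
            blocks.append(f)
            tag = sid if (replicate and subject_ids.count(sid) == 1) \
                else f"{sid}#rep{k}"
            sids.extend([tag] * f.shape[0])
            labs.extend([self.subject_label(sid)] * f.shape[0])
        return FrameSet(np.concatenate(blocks, axis=0), sids, labs,
                        self.freq_axis, self.channel_labels)

    def select_channels(self, channels) -> "FrameSet":
        """Restrict to a channel subset given as indices or labels."""
        idx = []
        for ch in channels:
            if isinstance(ch, str):
                if ch not in self.channel_labels:
                    raise KeyError(f"unknown channel label {ch!r}")
                idx.append(self.channel_labels.index(ch))
            else:
                if not 0 <= int(ch) < self.n_channels:
                    raise KeyError(f"channel index {ch} out of range")
                idx.append(int(ch))
        return FrameSet(self.frames[:, idx], self.subject_ids, self.labels,
                        self.freq_axis, [self.channel_labels[i] for i in idx])

    def label_array(self, class_names: list[str] | None = None) -> np.ndarray:
        """Integer class indices aligned to frames (sorted label order)."""
        names = class_names if class_names is not None else self.class_names
        lut = {c: i for i, c in enumerate(names)}
        return np.array([lut[l] for l in self.labels], dtype=int)


@dataclass
class NormalizationStats:
    """Per-(channel, frequency) centering/scaling fitted on training data."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: str = ""

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd shapes differ")
        if np.any(self.sd <= 0):
            raise ValueError("sd must be strictly positive (epsilon-floored)")
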