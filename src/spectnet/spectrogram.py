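"""EEG -> normalized spectrogram frames.

Each 1-s block of a channel is linearly detrended, Hann-windowed and
Fourier-transformed; amplitude bins in the 4-44 Hz band are aggregated to
2 Hz spacing, giving a 21-value epoch spectrum. Twenty consecutive epochs
per channel form one frame; frames slide by 1 s, and at most 148 frames
are kept per recording. Frames are finally centered and scaled to unit
variance per (channel, frequency) cell with statistics fitted on training
data only.

On the bin grid: a 1-s window gives native 1 Hz spectral spacing, so the
2 Hz analysis bins are formed by averaging consecutive non-overlapping
pairs of native bins starting at 4 Hz ((4,5), (6,7), ..., (44,45) Hz),
labeled by the lower (even) frequency of each pair. Band endpoints are
inclusive, which yields exactly 21 bins.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import (FRAME_EPOCHS, FRAMES_PER_SUBJECT, FREQ_MAX,
                         FREQ_MIN, FREQ_STEP, N_FREQ_BINS, EEGRecording,
                         FrameSet, NormalizationStats, default_freq_axis)

logger = logging.getLogger(__name__)

#: Variance floor used when a (channel, frequency) cell is constant.
NORMALIZATION_EPS = 1e-8


def detrend_segment(segment: np.ndarray,
                    sampling_rate: float | None = None) -> np.ndarray:
    """Remove the least-squares linear trend from one 1-s block.

    If ``sampling_rate`` is given, the segment length is validated against
    it (one block = sampling_rate samples).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be a 1-D sample vector")
    if sampling_rate is not None and len(segment) != int(sampling_rate):
        raise ValueError(
            f"segment has {len(segment)} samples, expected "
            f"{int(sampling_rate)} (one 1-s block)")
    return scipy.signal.detrend(segment, type="linear")


def epoch_spectrum(segment: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Hann-windowed FFT amplitude spectrum of one detrended 1-s block,
    aggregated to the 21-bin 4-44 Hz grid.

    Requires sampling_rate >= 2 * 44 + eps so the band is below Nyquist.
    """
    segment = np.asarray(segment, dtype=float)
    sr = int(round(sampling_rate))
    if sr < 2 * FREQ_MAX:
        raise ValueError(
            f"sampling rate {sampling_rate} S/s cannot resolve the "
            f"{FREQ_MIN}-{FREQ_MAX} Hz band (needs >= {2 * FREQ_MAX})")
    if len(segment) != sr:
        raise ValueError(
            f"segment has {len(segment)} samples, expected {sr}")
    window = scipy.signal.windows.hann(sr, sym=False)
    amp = np.abs(np.fft.rfft(segment * window))
    # native spacing is 1 Hz (1-s block); average consecutive pairs
    # (f, f+1) for f = 4, 6, ..., 44 into 2-Hz analysis bins.
    lows = np.arange(int(FREQ_MIN), int(FREQ_MAX) + 1, int(FREQ_STEP))
    out = 0.5 * (amp[lows] + amp[lows + 1])
    assert out.shape[0] == N_FREQ_BINS
    return out


def channel_spectrogram(channel_data: np.ndarray, sampling_rate: float,
                        detrend: bool = True) -> np.ndarray:
    """(freq_bins, n_epochs) amplitude spectrogram of one channel, from
    consecutive non-overlapping 1-s blocks."""
    sr = int(round(sampling_rate))
    n_epochs = len(channel_data) // sr
    cols = np.empty((N_FREQ_BINS, n_epochs))
    for e in range(n_epochs):
        block = channel_data[e * sr:(e + 1) * sr]
        if detrend:
            block = detrend_segment(block)
        cols[:, e] = epoch_spectrum(block, sr)
    return cols


def frame_count(duration_s: float, frame_length: int = FRAME_EPOCHS,
                max_frames: int | None = FRAMES_PER_SUBJECT) -> int:
    """Number of frames a recording yields: min(max, floor(T) - (L - 1))."""
    n = int(np.floor(duration_s)) - (frame_length - 1)
    if max_frames is not None:
        n = min(n, max_frames)
    return max(n, 0)


def screen_epochs(recording: EEGRecording,
                  amplitude_threshold: float) -> np.ndarray:
    """Optional amplitude-based epoch screen (extra utility, not part of
    the core pipeline): flags 1-s epochs whose peak absolute amplitude on
    any channel exceeds the threshold. Returns a boolean keep-mask over
    epochs."""
    sr = int(round(recording.sampling_rate))
    n_epochs = recording.data.shape[1] // sr
    keep = np.ones(n_epochs, dtype=bool)
    for e in range(n_epochs):
        block = recording.data[:, e * sr:(e + 1) * sr]
        if np.abs(block).max() > amplitude_threshold:
            keep[e] = False
    return keep


def build_frames(recording: EEGRecording, frame_length: int = FRAME_EPOCHS,
                 stride: int = 1,
                 max_frames: int | None = FRAMES_PER_SUBJECT,
                 detrend: bool = True) -> FrameSet:
    """Slice a recording into overlapping frames.

    Frames start at 0, stride, 2*stride, ... seconds; each consists of
    ``frame_length`` consecutive non-overlapping 1-s epoch spectra per
    channel. Epoch spectra are computed once on the 1-s grid and shared by
    the frames that overlap them.
    """
    if recording.duration < frame_length:
        raise ValueError(
            f"recording of {recording.duration:.1f} s is shorter than one "
            f"{frame_length}-s frame")
    spect = np.stack([
        channel_spectrogram(ch, recording.sampling_rate, detrend=detrend)
        for ch in recording.data
    ])  # (channels, freq_bins, total_epochs)
    total_epochs = spect.shape[2]
    starts = list(range(0, total_epochs - frame_length + 1, stride))
    if max_frames is not None:
        starts = starts[:max_frames]
    frames = np.stack([spect[:, :, s:s + frame_length] for s in starts])
    n = len(starts)
    return FrameSet(frames,
                    subject_ids=[recording.subject_id] * n,
                    labels=[recording.class_label] * n,
                    freq_axis=default_freq_axis(),
                    channel_labels=list(recording.channel_labels))


def build_frameset(recordings: list[EEGRecording], **kwargs) -> FrameSet:
    """Concatenate per-recording frames into one multi-subject FrameSet."""
    sets = [build_frames(rec, **kwargs) for rec in recordings]
    return FrameSet(
        np.concatenate([s.frames for s in sets]),
        np.concatenate([s.subject_ids for s in sets]),
        np.concatenate([s.labels for s in sets]),
        sets[0].freq_axis, sets[0].channel_labels)


class FrameNormalizer(BaseEstimator, TransformerMixin):
    """Center and scale frames per (channel, frequency) cell.

    Statistics are computed over all frames and epochs of the set passed to
    :meth:`fit` (the training set); :meth:`transform` applies them to any
    other frames. Cells with (near-)zero variance are floored at
    ``eps`` and a warning is logged: such a cell transforms to ~0.

    Parameters
    ----------
    eps : float
        Standard-deviation floor guarding constant cells.
    """

    def __init__(self, eps: float = NORMALIZATION_EPS):
        self.eps = eps

    @staticmethod
    def _as_array(frames) -> np.ndarray:
        x = frames.frames if isinstance(frames, FrameSet) else np.asarray(
            frames, dtype=float)
        if x.ndim != 4:
            raise ValueError("expected (n, channels, freq_bins, epochs)")
        return x

    def fit(self, X, y=None):
        x = self._as_array(X)
        if x.shape[0] == 0:
            raise ValueError("cannot fit normalization on an empty set")
        # statistics pool frames and epochs per (channel, freq) cell
        self.mean_ = x.mean(axis=(0, 3))
        sd = x.std(axis=(0, 3))
        n_floored = int(np.sum(sd < self.eps))
        if n_floored:
            msg = (f"{n_floored} (channel, frequency) cells have "
                   f"near-zero variance; flooring sd at {self.eps}")
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        self.sd_ = np.maximum(sd, self.eps)
        self.n_frames_in_ = x.shape[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        x = self._as_array(X)
        z = (x - self.mean_[None, :, :, None]) / self.sd_[None, :, :, None]
        if isinstance(X, FrameSet):
            return FrameSet(z, X.subject_ids, X.labels, X.freq_axis,
                            X.channel_labels)
        return z

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        x = self._as_array(X)
        return x * self.sd_[None, :, :, None] + self.mean_[None, :, :, None]

    def stats(self, fitted_on: str = "") -> NormalizationStats:
        check_is_fitted(self, "mean_")
        return NormalizationStats(self.mean_.copy(), self.sd_.copy(),
                                  fitted_on)


def fit_normalization(train: FrameSet,
                      fitted_on: str = "train") -> NormalizationStats:
    """Functional wrapper over :class:`FrameNormalizer` fitting."""
    return FrameNormalizer().fit(train).stats(fitted_on)


def apply_normalization(frames, stats: NormalizationStats):
    """Apply previously fitted statistics to frames (FrameSet or array)."""
    norm = FrameNormalizer()
    norm.mean_ = stats.mean
    norm.sd_ = stats.sd
    return norm.transform(frames)
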