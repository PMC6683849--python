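"""HDF5 persistence for recordings and framesets; EDF reading via MNE.

HDF5 layout for a FrameSet: ``frames`` (n, channels, freq, epochs) plus
aligned string datasets ``subject_ids``/``labels`` and axis metadata.
Recordings store the sample matrix with rate and label attributes. EDF
(the clinical acquisition format) is read through ``mne`` when available;
there is no EDF writer here.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .containers import EEGRecording, FrameSet

_STR = h5py.string_dtype(encoding="utf-8")


def save_frameset(frameset: FrameSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frameset.frames)
        f.create_dataset("subject_ids",
                         data=np.array(frameset.subject_ids, dtype=_STR))
        f.create_dataset("labels",
                         data=np.array(frameset.labels, dtype=_STR))
        f.create_dataset("freq_axis", data=frameset.freq_axis)
        f.create_dataset("channel_labels",
                         data=np.array(frameset.channel_labels, dtype=_STR))


def _decode(arr) -> np.ndarray:
    return np.array([v.decode() if isinstance(v, bytes) else str(v)
                     for v in arr], dtype=object)


def load_frameset(path: str | Path) -> FrameSet:
    with h5py.File(path, "r") as f:
        return FrameSet(f["frames"][()],
                        _decode(f["subject_ids"][()]),
                        _decode(f["labels"][()]),
                        f["freq_axis"][()],
                        list(_decode(f["channel_labels"][()])))


def save_recording(recording: EEGRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["class_label"] = recording.class_label
        f.create_dataset("channel_labels",
                         data=np.array(recording.channel_labels, dtype=_STR))


def load_recording(path: str | Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        return EEGRecording(f["data"][()],
                            float(f.attrs["sampling_rate"]),
                            list(_decode(f["channel_labels"][()])),
                            str(f.attrs["subject_id"]),
                            str(f.attrs["class_label"]))


def read_edf(path: str | Path, subject_id: str,
             class_label: str, channels: list[str] | None = None
             ) -> EEGRecording:
    """Read an EDF recording into an EEGRecording (requires mne)."""
    try:
        import mne
    except ImportError as err:                        # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package "
                          "(install the 'edf' extra)") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    data = raw.get_data() * 1e6                       # Volts -> microvolts
    return EEGRecording(data, float(raw.info["sfreq"]),
                        list(raw.ch_names), subject_id, class_label)
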