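"""Synthetic inputs with planted class structure, at two levels.

1. Spectrogram frames containing Gaussian radial bursts placed at random
   positions on the time axis with configurable jitter in frequency, width
   and amplitude — the development dataset on which the frame classifiers
   are validated. Two classes typically differ in burst center frequency
   (e.g., ~10 Hz alpha-like bursts vs ~6 Hz theta-like activity,
   mimicking the spectral slowing seen in neurodegeneration).
2. Raw multichannel EEG with class-dependent amplitude-modulated
   oscillatory bursts over white + 1/f background noise, so the entire
   pipeline (epoching, FFT, frame assembly) can be exercised end to end.

Subject structure: per-subject burst parameters are drawn once and then
re-jittered per frame, so frames within a subject are correlated — the
property that makes subject-aware cross-validation matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (FRAME_EPOCHS, FREQ_MAX, FREQ_MIN, N_FREQ_BINS,
                         EEGRecording, FrameSet, SpectrogramFrame,
                         default_freq_axis)

DEFAULT_FRAME_SHAPE = (1, N_FREQ_BINS, FRAME_EPOCHS)


@dataclass
class BurstSpec:
    """One family of Gaussian radial bursts on the spectrogram grid.

    Widths are Gaussian sigmas along each axis (time in epoch units, i.e.
    seconds; frequency in Hz). Jitter fractions perturb width and
    amplitude multiplicatively per burst; frequency jitter is additive in
    Hz. Defaults give the moderate-jitter regime used throughout.
    """

    center_frequency: float
    frequency_jitter_sd: float = 1.0
    burst_width_time: float = 1.0
    burst_width_freq: float = 2.0
    width_jitter_fraction: float = 0.2
    amplitude_mean: float = 1.0
    amplitude_jitter_fraction: float = 0.2
    bursts_per_frame_mean: float = 3.0

    def __post_init__(self):
        if not FREQ_MIN <= self.center_frequency <= FREQ_MAX:
            raise ValueError(
                f"center_frequency {self.center_frequency} Hz outside the "
                f"analysis band [{FREQ_MIN}, {FREQ_MAX}] Hz")
        for name in ("frequency_jitter_sd", "width_jitter_fraction",
                     "amplitude_jitter_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be > 0")
        if self.burst_width_time <= 0 or self.burst_width_freq <= 0:
            raise ValueError("burst widths must be > 0")
        if self.bursts_per_frame_mean < 0:
            raise ValueError("bursts_per_frame_mean must be >= 0")


@dataclass
class ClassRecipe:
    """Burst families plus background noise defining one class's frames.

    ``channels``: indices that carry the bursts (None = all channels);
    background noise is independent per channel either way.
    """

    label: str
    burst_specs: list[BurstSpec] = field(default_factory=list)
    background_noise_sd: float = 0.25
    channels: list[int] | None = None

    def __post_init__(self):
        if not self.burst_specs:
            raise ValueError("a ClassRecipe needs at least one BurstSpec")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")


def default_recipes() -> list[ClassRecipe]:
    """The two-class default task: alpha-like 10 Hz bursts vs slower,
    more persistent 6 Hz activity (wider in time, lower amplitude)."""
    return [
        ClassRecipe(label="A", burst_specs=[BurstSpec(center_frequency=10.0)]),
        ClassRecipe(label="B", burst_specs=[BurstSpec(
            center_frequency=6.0, burst_width_time=2.0)]),
    ]


def _add_burst(grid: np.ndarray, freq_axis: np.ndarray, f0: float,
               t0: float, sigma_f: float, sigma_t: float,
               amplitude: float) -> None:
    """Accumulate one 2-D Gaussian bump in place on a (freq, time) grid."""
    t_axis = np.arange(grid.shape[1], dtype=float)
    gf = np.exp(-0.5 * ((freq_axis - f0) / sigma_f) ** 2)
    gt = np.exp(-0.5 * ((t_axis - t0) / sigma_t) ** 2)
    grid += amplitude * np.outer(gf, gt)


def generate_burst_frame(recipe: ClassRecipe,
                         frame_shape: tuple[int, int, int] = DEFAULT_FRAME_SHAPE,
                         rng: np.random.Generator | int | None = None, *,
                         n_bursts: int | None = None,
                         positions: list[tuple[float, float]] | None = None
                         ) -> SpectrogramFrame:
    """One frame of background noise plus randomly placed Gaussian bursts.

    Burst counts are Poisson with the recipe's per-family mean; time
    positions uniform over the time axis; frequency, widths and amplitude
    each perturbed by their jitter. Amplitudes are clipped at zero.

    ``n_bursts``/``positions`` override randomness per family for
    deterministic construction (positions as (freq Hz, time epoch) pairs).
    """
    rng = np.random.default_rng(rng)
    n_ch, n_freq, n_t = frame_shape
    freq_axis = default_freq_axis()
    if n_freq != N_FREQ_BINS:
        freq_axis = np.linspace(FREQ_MIN, FREQ_MAX, n_freq)
    values = rng.normal(0.0, recipe.background_noise_sd,
                        size=frame_shape) if recipe.background_noise_sd > 0 \
        else np.zeros(frame_shape)
    channels = (list(range(n_ch)) if recipe.channels is None
                else list(recipe.channels))
    for ch in channels:
        if not 0 <= ch < n_ch:
            raise ValueError(f"burst channel {ch} out of range")
    for spec in recipe.burst_specs:
        k = rng.poisson(spec.bursts_per_frame_mean) if n_bursts is None \
            else n_bursts
        for b in range(k):
            if positions is not None:
                f0, t0 = positions[b % len(positions)]
            else:
                f0 = spec.center_frequency + rng.normal(
                    0.0, spec.frequency_jitter_sd) \
                    if spec.frequency_jitter_sd > 0 else spec.center_frequency
                t0 = rng.uniform(0.0, n_t - 1)
            wj = 1.0 + (rng.normal(0.0, spec.width_jitter_fraction)
                        if spec.width_jitter_fraction > 0 else 0.0)
            aj = 1.0 + (rng.normal(0.0, spec.amplitude_jitter_fraction)
                        if spec.amplitude_jitter_fraction > 0 else 0.0)
            sigma_t = max(spec.burst_width_time * wj, 0.1)
            sigma_f = max(spec.burst_width_freq * wj, 0.1)
            amp = max(spec.amplitude_mean * aj, 0.0)
            for ch in channels:
                _add_burst(values[ch], freq_axis, f0, t0, sigma_f, sigma_t,
                           amp)
    np.clip(values, 0.0, None, out=values)
    return SpectrogramFrame(values, freq_axis)


def _subject_variant(spec: BurstSpec, rng: np.random.Generator) -> BurstSpec:
    """Draw subject-level burst parameters around the population spec.

    Each jitter SD is split evenly in variance between the subject draw
    and the per-frame draw (both get sd/sqrt(2)), so the total
    frame-to-frame spread matches the configured jitter while frames
    within a subject stay correlated.
    """
    h = 1.0 / np.sqrt(2.0)
    f0 = float(np.clip(
        spec.center_frequency
        + rng.normal(0.0, h * spec.frequency_jitter_sd),
        FREQ_MIN, FREQ_MAX))
    amp = max(spec.amplitude_mean
              * (1.0 + rng.normal(0.0, h * spec.amplitude_jitter_fraction)),
              0.05 * spec.amplitude_mean)
    wj = 1.0 + rng.normal(0.0, h * spec.width_jitter_fraction)
    return replace(spec, center_frequency=f0, amplitude_mean=amp,
                   burst_width_time=max(spec.burst_width_time * wj, 0.1),
                   burst_width_freq=max(spec.burst_width_freq * wj, 0.1),
                   frequency_jitter_sd=h * spec.frequency_jitter_sd,
                   width_jitter_fraction=h * spec.width_jitter_fraction,
                   amplitude_jitter_fraction=h * spec.amplitude_jitter_fraction)


def generate_class_frameset(recipes: list[ClassRecipe],
                            n_subjects_per_class: int,
                            frames_per_subject: int,
                            rng_seed: int | np.random.Generator = 0,
                            frame_shape: tuple[int, int, int] = DEFAULT_FRAME_SHAPE
                            ) -> FrameSet:
    """Subject-grouped frameset: per subject, burst parameters are drawn
    once (a subject 'phenotype'), then each frame re-jitters around them."""
    if frames_per_subject < 1:
        raise ValueError("frames_per_subject must be >= 1")
    if n_subjects_per_class < 1:
        raise ValueError("n_subjects_per_class must be >= 1")
    rng = np.random.default_rng(rng_seed)
    frames, sids, labels = [], [], []
    for recipe in recipes:
        for s in range(n_subjects_per_class):
            subject_specs = [_subject_variant(sp, rng)
                             for sp in recipe.burst_specs]
            subject_recipe = replace(recipe, burst_specs=subject_specs)
            sid = f"{recipe.label}-s{s:03d}"
            for _ in range(frames_per_subject):
                fr = generate_burst_frame(subject_recipe, frame_shape, rng)
                frames.append(fr.values)
                sids.append(sid)
                labels.append(recipe.label)
    return FrameSet(np.stack(frames), sids, labels,
                    freq_axis=default_freq_axis() if
                    frame_shape[1] == N_FREQ_BINS else
                    np.linspace(FREQ_MIN, FREQ_MAX, frame_shape[1]))


# ---------------------------------------------------------------------------
# raw-signal level
# ---------------------------------------------------------------------------

@dataclass
class OscillationRecipe:
    """Class-dependent oscillatory bursting in the raw signal: sinusoidal
    carrier under Gaussian envelopes at Poisson onset times."""

    carrier_frequency: float          # Hz
    burst_duration: float = 1.0       # envelope sigma, s
    burst_rate: float = 0.5           # expected bursts per s per channel
    amplitude: float = 1.0            # carrier peak amplitude, a.u.


@dataclass
class EEGSynthConfig:
    """Raw synthetic EEG: geometry, per-class oscillations, noise."""

    n_channels: int = 14
    sampling_rate: float = 256.0
    duration: float = 167.0           # s; 167 s -> 148 frames
    recipes: dict[str, OscillationRecipe] = field(default_factory=lambda: {
        "A": OscillationRecipe(carrier_frequency=10.0, burst_duration=0.5,
                               burst_rate=0.6, amplitude=2.0),
        "B": OscillationRecipe(carrier_frequency=6.0, burst_duration=1.5,
                               burst_rate=0.4, amplitude=2.0),
    })
    white_noise_sd: float = 0.5
    pink_noise_amplitude: float = 0.5

    def __post_init__(self):
        if self.sampling_rate <= 2 * FREQ_MAX:
            raise ValueError(
                "sampling_rate must exceed twice the top analysis "
                f"frequency ({2 * FREQ_MAX} S/s)")
        if self.duration < FRAME_EPOCHS:
            raise ValueError(
                f"duration {self.duration} s cannot produce one "
                f"{FRAME_EPOCHS}-s frame")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit peak std."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:] / f[1])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_synthetic_eeg(config: EEGSynthConfig, class_label: str,
                           rng_seed: int | np.random.Generator = 0,
                           subject_id: str = "synth-000") -> EEGRecording:
    """One multichannel recording with the class's oscillatory bursts.

    Each channel independently receives Poisson-timed bursts: a carrier
    sinusoid with random phase under a Gaussian amplitude envelope, summed
    with white and 1/f background noise.
    """
    if class_label not in config.recipes:
        raise KeyError(f"no oscillation recipe for class {class_label!r}")
    rng = np.random.default_rng(rng_seed)
    rec = config.recipes[class_label]
    sr = config.sampling_rate
    n = int(round(config.duration * sr))
    t = np.arange(n) / sr
    data = np.zeros((config.n_channels, n))
    for ch in range(config.n_channels):
        sig = np.zeros(n)
        n_bursts = rng.poisson(rec.burst_rate * config.duration)
        onsets = rng.uniform(0.0, config.duration, size=n_bursts)
        for t0 in onsets:
            if rec.amplitude <= 0:
                continue
            phase = rng.uniform(0.0, 2 * np.pi)
            env = np.exp(-0.5 * ((t - t0) / rec.burst_duration) ** 2)
            sig += rec.amplitude * env * np.sin(
                2 * np.pi * rec.carrier_frequency * t + phase)
        if config.white_noise_sd > 0:
            sig += rng.normal(0.0, config.white_noise_sd, size=n)
        if config.pink_noise_amplitude > 0:
            sig += config.pink_noise_amplitude * _pink_noise(n, rng)
        data[ch] = sig
    labels = [f"ch{i}" for i in range(config.n_channels)]
    return EEGRecording(data, sr, labels, subject_id, class_label)


def generate_eeg_cohort(config: EEGSynthConfig, n_subjects_per_class: int,
                        rng_seed: int = 0) -> list[EEGRecording]:
    """A labeled cohort of recordings, one per synthetic subject."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for label in sorted(config.recipes):
        for s in range(n_subjects_per_class):
            child = rng.integers(0, 2 ** 31)
            out.append(generate_synthetic_eeg(
                config, label, int(child), subject_id=f"{label}-s{s:03d}"))
    return out
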