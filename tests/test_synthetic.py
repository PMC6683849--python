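"""Synthetic burst generators: planted structure, determinism, statistics."""

import numpy as np
import pytest

import spectnet as sn
from spectnet.synthetic import (BurstSpec, ClassRecipe, EEGSynthConfig,
                                generate_burst_frame,
                                generate_class_frameset,
                                generate_synthetic_eeg)


def _clean_spec(**kw):
    base = dict(center_frequency=10.0, frequency_jitter_sd=0.0,
                width_jitter_fraction=0.0, amplitude_jitter_fraction=0.0,
                bursts_per_frame_mean=1.0)
    base.update(kw)
    return BurstSpec(**base)


class TestBurstFrame:
    def test_deterministic_peak_placement(self):
        """Zero jitter, zero noise, one burst at 10 Hz / epoch 10: the
        global maximum sits exactly there."""
        recipe = ClassRecipe("A", [_clean_spec()], background_noise_sd=0.0)
        frame = generate_burst_frame(recipe, rng=0, n_bursts=1,
                                     positions=[(10.0, 10.0)])
        ch, fbin, ep = np.unravel_index(frame.values.argmax(),
                                        frame.values.shape)
        assert frame.freq_axis[fbin] == 10.0
        assert ep == 10

    def test_empty_recipe_gives_zero_frame(self):
        recipe = ClassRecipe(
            "A", [_clean_spec(bursts_per_frame_mean=0.0)],
            background_noise_sd=0.0)
        frame = generate_burst_frame(recipe, rng=1)
        np.testing.assert_array_equal(frame.values, 0.0)

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ValueError, match="analysis band"):
            BurstSpec(center_frequency=50.0)
        with pytest.raises(ValueError, match="analysis band"):
            BurstSpec(center_frequency=2.0)

    def test_frames_are_nonnegative(self):
        recipe = ClassRecipe("A", [BurstSpec(10.0)])
        for seed in range(5):
            frame = generate_burst_frame(recipe, rng=seed)
            assert np.all(frame.values >= 0)

    def test_poisson_burst_count_mean(self):
        """Empirical burst-count mean within 3 SE of the configured mean.

        Counted through total planted mass: each zero-jitter burst
        deposits identical mass, so mass / unit-mass = count."""
        spec = _clean_spec(bursts_per_frame_mean=3.0)
        one = ClassRecipe("A", [spec], 0.0)
        unit = generate_burst_frame(one, rng=0, n_bursts=1,
                                    positions=[(10.0, 9.5)]).values.sum()
        n_frames = 2000
        rng = np.random.default_rng(11)
        counts = []
        for _ in range(n_frames):
            total = generate_burst_frame(one, rng=rng).values.sum()
            counts.append(total / unit)
        mean = np.mean(counts)
        se = np.sqrt(3.0 / n_frames)   # Poisson variance = mean
        # mass-based count is approximate near the grid edge; 3 SE plus
        # a small discretization allowance
        assert abs(mean - 3.0) < 3 * se + 0.15

    def test_class_separation_by_dominant_band_oracle(self):
        """Brute-force oracle: the dominant frequency band of the
        time-averaged spectrum (energy within one burst width of each
        planted center) separates 10 Hz from 6 Hz frames with accuracy
        > 0.9. Frames that happen to draw zero bursts are pure noise and
        bound the attainable accuracy below 100%."""
        rng = np.random.default_rng(5)
        rec_a = ClassRecipe("A", [BurstSpec(10.0)])
        rec_b = ClassRecipe("B", [BurstSpec(6.0)])
        freqs = sn.default_freq_axis()

        def band(profile, center):
            return profile[np.abs(freqs - center) <= 2.0].sum()

        correct = 0
        n = 1000
        for _ in range(n):
            fa = generate_burst_frame(rec_a, rng=rng).values.mean(axis=(0, 2))
            fb = generate_burst_frame(rec_b, rng=rng).values.mean(axis=(0, 2))
            correct += band(fa, 10.0) >= band(fa, 6.0)
            correct += band(fb, 6.0) > band(fb, 10.0)
        assert correct / (2 * n) > 0.9


class TestFrameset:
    def test_counts(self):
        fs = generate_class_frameset(sn.default_recipes(), 10, 148,
                                     rng_seed=0)
        assert len(fs.subjects) == 20
        assert len(fs) == 2960
        for sid in fs.subjects:
            assert (fs.subject_ids == sid).sum() == 148

    def test_same_seed_identical(self):
        a = generate_class_frameset(sn.default_recipes(), 3, 10, rng_seed=9)
        b = generate_class_frameset(sn.default_recipes(), 3, 10, rng_seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.subject_ids, b.subject_ids)

    def test_within_subject_correlation_exceeds_between(self):
        """Subject-level parameter draws make frames within a subject
        more alike than frames across subjects of the same class."""
        fs = generate_class_frameset(
            [sn.ClassRecipe("A", [sn.BurstSpec(10.0,
                                               frequency_jitter_sd=2.0)])],
            n_subjects_per_class=6, frames_per_subject=30, rng_seed=3)
        freqs = sn.default_freq_axis()
        peak = freqs[fs.frames.mean(axis=(1, 3)).argmax(axis=1)]
        subjects = np.asarray(fs.subject_ids)
        within = np.var([peak[subjects == s].mean()
                         for s in fs.subjects])
        total = np.var(peak)
        pooled_within = np.mean([peak[subjects == s].var()
                                 for s in fs.subjects])
        assert pooled_within < total  # subject effect absorbs variance

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_class_frameset(sn.default_recipes(), 2, 0)
        with pytest.raises(ValueError):
            ClassRecipe("A", [])


class TestSyntheticEEG:
    def test_pure_tone_spectrogram_peaks_at_tone(self):
        cfg = EEGSynthConfig(n_channels=2, duration=25.0,
                             white_noise_sd=0.0, pink_noise_amplitude=0.0,
                             recipes={"A": sn.OscillationRecipe(
                                 carrier_frequency=10.0, amplitude=0.0)})
        rec = generate_synthetic_eeg(cfg, "A", rng_seed=0)
        t = np.arange(rec.data.shape[1]) / rec.sampling_rate
        rec.data[:] = np.sin(2 * np.pi * 10.0 * t)
        fs = sn.build_frames(rec, max_frames=None)
        freqs = sn.default_freq_axis()
        peaks = freqs[fs.frames.argmax(axis=2)]
        assert np.all(peaks == 10.0)

    def test_zero_amplitude_zero_noise_is_silent(self):
        cfg = EEGSynthConfig(n_channels=3, duration=21.0,
                             white_noise_sd=0.0, pink_noise_amplitude=0.0,
                             recipes={"A": sn.OscillationRecipe(
                                 carrier_frequency=10.0, amplitude=0.0)})
        rec = generate_synthetic_eeg(cfg, "A", rng_seed=4)
        np.testing.assert_array_equal(rec.data, 0.0)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            EEGSynthConfig(duration=10.0)

    def test_length_and_determinism(self):
        cfg = EEGSynthConfig(n_channels=2, duration=30.0)
        a = generate_synthetic_eeg(cfg, "A", rng_seed=5)
        b = generate_synthetic_eeg(cfg, "A", rng_seed=5)
        assert a.data.shape == (2, 30 * 256)
        np.testing.assert_array_equal(a.data, b.data)

    def test_full_pipeline_on_raw_eeg_reaches_95pct_frame_accuracy(self):
        """167-s recordings of 10 Hz-burst vs 6 Hz-burst classes, run
        through epoching/FFT/frame assembly and the convolutional
        classifier, give held-out frame accuracy in the 95-100% range."""
        cfg = sn.EEGSynthConfig(n_channels=1, duration=167.0)
        recs = sn.generate_eeg_cohort(cfg, n_subjects_per_class=6,
                                      rng_seed=50)
        fs = sn.build_frameset(recs)
        assert len(fs) == 12 * 148
        summary = sn.run_experiments(
            fs, lambda s: sn.DCNNClassifier(n_steps=400, random_state=s),
            n_experiments=2, rng_seed=3)
        assert summary.test_frame_accuracy[0] >= 0.95

    def test_class_bursts_visible_in_band(self):
        """10 Hz-burst recordings carry more 10 Hz than 6 Hz energy and
        vice versa, through the full spectrogram pipeline."""
        cfg = EEGSynthConfig(n_channels=1, duration=40.0)
        freqs = sn.default_freq_axis()
        i10 = int(np.where(freqs == 10.0)[0][0])
        i6 = int(np.where(freqs == 6.0)[0][0])
        ra = generate_synthetic_eeg(cfg, "A", rng_seed=21)  # 10 Hz bursts
        rb = generate_synthetic_eeg(cfg, "B", rng_seed=22)  # 6 Hz bursts
        sa = sn.build_frames(ra, max_frames=None).frames.mean(axis=(0, 1, 3))
        sb = sn.build_frames(rb, max_frames=None).frames.mean(axis=(0, 1, 3))
        assert sa[i10] > sa[i6]
        assert sb[i6] > sb[i10]
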