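"""Leave-pair-out machinery: splits, balancing, scoring, AUC, the
experiment loop and the channel sweep."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import spectnet as sn
from spectnet.evaluation import (balance_by_replication, make_lpo_split,
                                 permute_subject_labels, score_subject,
                                 wmw_auc)


def _labels(n_a, n_b):
    d = {f"a{i}": "HC" for i in range(n_a)}
    d.update({f"b{i}": "PD" for i in range(n_b)})
    return d


class TestLPOSplit:
    def test_balances_74_vs_14_to_73_73(self):
        split = make_lpo_split(_labels(74, 14), rng=0)
        assert len(split.test_pair) == 2
        train = np.asarray(split.train_subjects)
        hc = [s for s in train if s.startswith("a")]
        pd_ = [s for s in train if s.startswith("b")]
        assert len(hc) == 73 and len(pd_) == 73
        assert len(set(hc)) == 73          # majority class: no replication
        assert len(set(pd_)) == 13         # minority: replicated copies

    def test_minimal_two_by_two(self):
        split = make_lpo_split(_labels(2, 2), rng=1)
        assert len(split.train_subjects) == 2

    def test_single_subject_class_rejected(self):
        with pytest.raises(ValueError, match="need >= 2"):
            make_lpo_split(_labels(3, 1), rng=0)

    def test_no_leakage_over_1000_seeded_splits(self):
        labels = _labels(9, 4)
        rng = np.random.default_rng(42)
        for _ in range(1000):
            split = make_lpo_split(labels, rng)
            assert not (set(split.test_pair.values())
                        & set(split.train_subjects))

    def test_test_pair_frequency_is_uniform(self):
        """Held-out subjects are drawn uniformly within each class: a
        chi-square goodness-of-fit audit of hold-out frequencies over
        1,000 splits does not reject uniformity (and each subject stays
        within generous binomial bounds)."""
        from scipy.stats import chi2
        labels = _labels(8, 5)
        rng = np.random.default_rng(7)
        counts = {s: 0 for s in labels}
        n = 1000
        for _ in range(n):
            split = make_lpo_split(labels, rng)
            for s in split.test_pair.values():
                counts[s] += 1
        for size, prefix in ((8, "a"), (5, "b")):
            obs = np.array([c for s, c in sorted(counts.items())
                            if s.startswith(prefix)])
            expected = n / size
            stat = ((obs - expected) ** 2 / expected).sum()
            assert stat < chi2.ppf(0.999, df=size - 1)
            # no subject is wildly over/under-selected (4-sigma screen)
            p = 1.0 / size
            assert np.all(np.abs(obs - n * p)
                          < 4 * np.sqrt(p * (1 - p) * n))

    def test_replication_materializes_frames(self, small_frameset):
        labels = small_frameset.subject_labels()
        split = make_lpo_split(labels, rng=3)
        # force imbalance: drop one class's subjects to 2
        split.train_subjects = (
            [s for s in split.train_subjects if s.startswith("A")]
            + [s for s in split.train_subjects if s.startswith("B")][:2] * 1)
        train, test = balance_by_replication(small_frameset, split)
        assert len(train) == 24 * len(split.train_subjects)
        assert len(test) == 2 * 24


class TestSubjectScore:
    def test_mean_of_constant_rows(self):
        s = score_subject(np.tile([0.8, 0.2], (5, 1)), "s", "c0",
                          ["c0", "c1"])
        np.testing.assert_allclose(s.probabilities, [0.8, 0.2])
        assert s.predicted_label == "c0" and s.correct

    def test_exact_tie_goes_to_first_class(self):
        s = score_subject(np.array([[1.0, 0.0], [0.0, 1.0]]), "s", "c1",
                          ["c0", "c1"])
        np.testing.assert_allclose(s.probabilities, [0.5, 0.5])
        assert s.predicted_label == "c0"

    def test_mean_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        raw = rng.random((148, 2))
        probs = raw / raw.sum(axis=1, keepdims=True)
        s = score_subject(probs)
        oracle = np.array([probs[:, 0].sum() / 148, probs[:, 1].sum() / 148])
        np.testing.assert_allclose(s.probabilities, oracle, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            score_subject(np.empty((0, 2)))


class TestWMWAUC:
    def test_perfect_separation(self):
        assert wmw_auc([0.9, 0.8], [0.2, 0.3]) == 1.0

    def test_all_ties_is_half(self):
        assert wmw_auc([0.5] * 4, [0.5] * 6) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wmw_auc([], [0.1])

    def test_matches_roc_integration_oracle(self):
        """Pair counting equals trapezoidal ROC integration (sklearn's
        roc_auc_score) to 1e-12 on random score sets with ties."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            s1 = np.round(rng.random(50), 2)   # rounding forces ties
            s0 = np.round(rng.random(50), 2)
            y = np.r_[np.ones(50), np.zeros(50)]
            ours = wmw_auc(s1, s0)
            oracle = roc_auc_score(y, np.r_[s1, s0])
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s1, s0 = rng.random(30), rng.random(40)
        base = wmw_auc(s1, s0)
        for f in (np.exp, lambda v: v ** 3, lambda v: 5 * v - 2):
            assert wmw_auc(f(s1), f(s0)) == pytest.approx(base, abs=1e-12)


class TestExperimentLoop:
    def test_single_experiment_has_zero_sd(self, small_frameset):
        summ = sn.run_experiments(
            small_frameset,
            lambda s: sn.DCNNClassifier(n_steps=60, random_state=s),
            n_experiments=1, rng_seed=0)
        assert summ.test_frame_accuracy[1] == 0.0
        assert summ.subject_accuracy[1] == 0.0

    def test_fold_subject_accuracy_support(self, small_frameset):
        summ = sn.run_experiments(
            small_frameset,
            lambda s: sn.DCNNClassifier(n_steps=60, random_state=s),
            n_experiments=3, rng_seed=1)
        for fold in summ.folds:
            assert fold.subject_accuracy in (0.0, 0.5, 1.0)
            assert len(fold.subject_scores) == 2
        pooled = np.mean([s.correct for f in summ.folds
                          for s in f.subject_scores])
        assert summ.subject_accuracy[0] == pytest.approx(pooled)

    def test_metrics_within_unit_interval(self, small_frameset):
        summ = sn.run_experiments(
            small_frameset,
            lambda s: sn.ShallowClassifier(n_steps=40, random_state=s),
            n_experiments=2, rng_seed=2)
        d = summ.to_dict()
        for key, v in d.items():
            if key.endswith(("mean", "auc")):
                assert 0.0 <= v <= 1.0


class TestChannelSweep:
    @pytest.fixture(scope="class")
    def planted_fs(self):
        """Four channels; bursts planted only in channels 0-1."""
        recipes = [
            sn.ClassRecipe("A", [sn.BurstSpec(10.0)], channels=[0, 1]),
            sn.ClassRecipe("B", [sn.BurstSpec(6.0)], channels=[0, 1]),
        ]
        return sn.generate_class_frameset(recipes, 3, 12, rng_seed=5,
                                          frame_shape=(4, 21, 20))

    def test_planted_channels_rank_top(self, planted_fs):
        table = sn.channel_sweep(
            planted_fs, [0, 1, 2, 3],
            lambda s: sn.ShallowClassifier(n_steps=120, random_state=s),
            n_experiments_per_channel=2, rng_seed=0)
        ranked = table.sort_values("auc", ascending=False)
        assert set(ranked["channel"].iloc[:2]) == {"ch0", "ch1"}

    def test_sweep_independent_of_order(self, planted_fs):
        builder = lambda s: sn.ShallowClassifier(n_steps=40, random_state=s)
        t1 = sn.channel_sweep(planted_fs, [0, 2], builder, 1, rng_seed=1)
        t2 = sn.channel_sweep(planted_fs, [2, 0], builder, 1, rng_seed=1)
        a = t1.set_index("channel").loc[["ch0", "ch2"]]
        b = t2.set_index("channel").loc[["ch0", "ch2"]]
        np.testing.assert_allclose(a["auc"].values, b["auc"].values)
        np.testing.assert_allclose(a["test_frame_accuracy_mean"].values,
                                   b["test_frame_accuracy_mean"].values)

    def test_single_channel_sweep_consistent_with_run(self, planted_fs):
        builder = lambda s: sn.ShallowClassifier(n_steps=40, random_state=s)
        table = sn.channel_sweep(planted_fs, [1], builder, 2, rng_seed=2)
        assert len(table) == 1
        assert 0.0 <= table["auc"].iloc[0] <= 1.0

    def test_unknown_channel_rejected(self, planted_fs):
        with pytest.raises(KeyError, match="unknown channel"):
            sn.channel_sweep(planted_fs, ["nope"],
                             lambda s: sn.ShallowClassifier(n_steps=5),
                             1, rng_seed=0)


def test_permuted_labels_preserve_counts(small_frameset):
    perm = permute_subject_labels(small_frameset, rng=0)
    assert sorted(perm.labels) == sorted(small_frameset.labels)
    # still constant within subject
    for sid in perm.subjects:
        assert len(set(perm.labels[perm.subject_ids == sid])) == 1
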