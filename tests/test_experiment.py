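"""Split schemes, checkpointing, training determinism and the paired test."""

import numpy as np
import pytest
from scipy import stats

from eegtrm.backbones import build_from_registry
from eegtrm.experiment import (
    RunResult,
    SplitScheme,
    TrainingConfig,
    compare,
    select_checkpoint,
    split,
    summarize,
    train_eval,
)
from eegtrm.montage import EpochSet


def balanced_epochs(n_trials, n_channels=3, tp=8, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(n_classes), n_trials // n_classes)
    return EpochSet(rng.normal(size=(n_trials, n_channels, tp)), labels, 100.0,
                    tuple(f"c{i}" for i in range(n_channels)))


class TestSplit:
    def test_cv4_shapes_on_80_trials(self):
        folds = split(balanced_epochs(80), SplitScheme("cv4", seed=0))
        assert len(folds) == 4
        for f in folds:
            assert (len(f.train), len(f.val), len(f.test)) == (40, 20, 20)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 100)) // 4 * 4
        ep = balanced_epochs(n, seed=seed)
        for f in split(ep, SplitScheme("cv4", seed=seed)):
            union = np.concatenate([f.train, f.val, f.test])
            assert sorted(union.tolist()) == list(range(n))
            assert not set(f.train) & set(f.val)
            assert not set(f.train) & set(f.test)
            assert not set(f.val) & set(f.test)

    def test_cv4_role_rotation(self):
        """Quarter i tests fold i and validates fold i-1 (mod 4)."""
        folds = split(balanced_epochs(40), SplitScheme("cv4", seed=3))
        for i in range(4):
            np.testing.assert_array_equal(folds[i].val, folds[(i + 1) % 4].test)

    def test_fixed_test_80_20(self):
        ep = balanced_epochs(1040)
        test_idx = tuple(range(880, 1040))
        folds = split(ep, SplitScheme("fixed-test", seed=0, test_indices=test_idx))
        assert len(folds) == 4
        for f in folds:
            assert (len(f.train), len(f.val), len(f.test)) == (704, 176, 160)
            np.testing.assert_array_equal(f.test, np.arange(880, 1040))

    def test_stratification(self):
        ep = balanced_epochs(40)
        for f in split(ep, SplitScheme("cv4", seed=1)):
            for idx in (f.train, f.val, f.test):
                assert set(ep.labels[idx]) == {0, 1}

    def test_class_too_small_for_cv4(self):
        ep = balanced_epochs(8)
        ep.labels[:] = 0
        ep.labels[0] = 1  # one lone trial of class 1
        with pytest.raises(ValueError, match="stratification"):
            split(ep, SplitScheme("cv4", seed=0))


class TestCheckpointSelection:
    @pytest.mark.parametrize(
        "losses, best",
        [
            ([3.0, 2.0, 1.0, 4.0], 2),
            ([1.0, 1.0, 1.0], 0),        # strict improvement only: first stays
            ([5.0], 0),
            ([2.0, 1.0, 1.0, 0.5, 0.9], 3),
        ],
    )
    def test_minimum_validation_loss_rule(self, losses, best):
        assert select_checkpoint(losses) == best

    def test_reported_accuracy_comes_from_checkpoint_not_last_epoch(
        self, small_montage, easy_small_epochs
    ):
        """Train past convergence; best epoch recorded must match the argmin
        of the stored validation curve, not the final epoch."""
        folds = split(easy_small_epochs, SplitScheme("cv4", seed=0))[:1]
        res = train_eval(
            lambda s: build_from_registry("compact", small_montage, 100, 2, seed=s),
            folds, easy_small_epochs, TrainingConfig(max_epochs=4, seed=0),
        )
        assert res.best_epochs[0] == int(np.argmin(res.val_curves[0])) + 1


class TestTrainEval:
    def test_one_epoch_curves_and_checkpoint(self, small_montage, easy_small_epochs):
        folds = split(easy_small_epochs, SplitScheme("cv4", seed=0))[:1]
        res = train_eval(
            lambda s: build_from_registry("compact", small_montage, 100, 2, seed=s),
            folds, easy_small_epochs, TrainingConfig(max_epochs=1, seed=0),
        )
        assert len(res.train_curves[0]) == 1
        assert len(res.val_curves[0]) == 1
        assert res.best_epochs == [1]

    def test_same_seed_identical_results(self, small_montage, easy_small_epochs):
        folds = split(easy_small_epochs, SplitScheme("cv4", seed=1))[:2]
        factory = lambda s: build_from_registry(  # noqa: E731
            "shallow+trm-3", small_montage, 100, 2, seed=s)
        cfg = TrainingConfig(max_epochs=2, seed=5)
        a = train_eval(factory, folds, easy_small_epochs, cfg)
        b = train_eval(factory, folds, easy_small_epochs, cfg)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.train_curves == b.train_curves
        assert a.val_curves == b.val_curves
        assert a.best_epochs == b.best_epochs

    def test_easy_data_trains_above_chance(self, small_montage, easy_small_epochs):
        """Spatially separable data: a TRM-fronted net fits within tens of
        epochs at small scale."""
        folds = split(easy_small_epochs, SplitScheme("cv4", seed=2))[:1]
        res = train_eval(
            lambda s: build_from_registry("shallow+trm-3", small_montage, 100, 2,
                                          seed=s),
            folds, easy_small_epochs, TrainingConfig(max_epochs=60, seed=1),
        )
        assert res.fold_accuracies[0] > 75.0
        assert res.parameter_count > 0


class TestCompare:
    def test_identical_pairs(self):
        r = compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == 0.0
        assert r.p_value == 1.0

    def test_closed_form_example(self):
        """d = [1,2,3,4]: t = 2.5 / (1.29099.../2) = 3.873."""
        a = np.array([2.0, 4.0, 6.0, 8.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        r = compare(a, b)
        assert r.mean_difference == pytest.approx(2.5)
        assert r.t_statistic == pytest.approx(3.8729833, rel=1e-6)

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r1, r2 = compare(a, b), compare(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_agreement_with_scipy_on_100_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            ours = compare(a, b)
            ref = stats.ttest_rel(a, b)
            assert ours.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_nonzero_mean_degenerate(self):
        r = compare([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.degenerate
        assert np.isnan(r.p_value)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="pairing"):
            compare([1.0, 2.0], [1.0])


def _fake_run(accs):
    return RunResult(list(accs), [], [], [], parameter_count=1)


class TestSummarize:
    def test_deltas_by_hand_on_two_subjects(self):
        results = {
            ("s1", "shallow"): _fake_run([80.0, 82.0]),
            ("s2", "shallow"): _fake_run([70.0, 72.0]),
            ("s1", "shallow+trm-5"): _fake_run([85.0, 87.0]),
            ("s2", "shallow+trm-5"): _fake_run([74.0, 76.0]),
        }
        s = summarize(results)
        # originals average (81+71)/2 = 76; variant (86+75)/2 = 80.5
        assert s.deltas["shallow+trm-5"] == pytest.approx(4.5)
        assert s.averages["shallow"] == pytest.approx(76.0)
        assert 0.0 <= s.p_values["shallow+trm-5"] <= 1.0

    def test_single_fold_flagged(self):
        s = summarize({("s1", "deep"): _fake_run([90.0])})
        assert "single fold" in s.table.loc["s1", "deep"]

    def test_missing_cells_left_as_gaps(self):
        s = summarize({
            ("s1", "compact"): _fake_run([60.0, 62.0]),
            ("s1", "compact+trm-3"): _fake_run([65.0, 66.0]),
            ("s2", "compact"): _fake_run([55.0, 57.0]),
        })
        assert s.means.loc["s2", "compact+trm-3"] != s.means.loc["s2", "compact"]
        assert np.isnan(s.means.loc["s2", "compact+trm-3"])
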