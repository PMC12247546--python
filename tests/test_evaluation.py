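"""Fold plans, nested CV with stub classifiers, confusion aggregation,
binomial/empirical chance levels and the paired accuracy test."""

import numpy as np
import pytest
from scipy import stats

from megdecode.containers import EpochSet
from megdecode.evaluation import (DegenerateTestError, EvalReport,
                                  aggregate_confusion,
                                  binomial_chance_threshold, empirical_chance,
                                  loso_cv, make_fold_plan, nested_cv,
                                  paired_accuracy_test)


def _epochs(n=300, k=5, seed=0, n_ch=2, n_s=10):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), n // k)
    rng.shuffle(labels)
    data = rng.standard_normal((n, n_ch, n_s))
    # embed the label so oracle classifiers can read it off
    data[:, 0, 0] = labels
    return EpochSet(data=data, labels=labels, sfreq=5.0, window=(-1.0, 1.0))


class OracleClassifier:
    """Reads the true label embedded in the data (test stub)."""

    def fit(self, train_set, val_set):
        return self

    def predict(self, data):
        return data[:, 0, 0].astype(int)


class ConstantClassifier:
    def __init__(self, klass=0):
        self.klass = klass

    def fit(self, train_set, val_set):
        return self

    def predict(self, data):
        return np.full(len(data), self.klass)


class TestFoldPlan:
    def test_balanced_fold_sizes(self):
        ep = _epochs()
        plan = make_fold_plan(300, ep.labels, seed=0)
        for fold in plan.folds + [plan.test_idx]:
            assert len(fold) == 30
            assert np.all(np.bincount(ep.labels[fold], minlength=5) == 6)

    def test_same_seed_identical_plans(self):
        ep = _epochs()
        p1 = make_fold_plan(300, ep.labels, seed=42)
        p2 = make_fold_plan(300, ep.labels, seed=42)
        np.testing.assert_array_equal(p1.test_idx, p2.test_idx)
        for a, b in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(a, b)

    def test_partition_properties_sweep(self):
        # disjointness + coverage over many random plans
        ep = _epochs(n=100, k=5, seed=3)
        for seed in range(100):
            plan = make_fold_plan(100, ep.labels, seed=seed)
            parts = plan.folds + [plan.test_idx]
            allidx = np.concatenate(parts)
            assert len(allidx) == 100
            assert set(allidx.tolist()) == set(range(100))
            for i in range(len(parts)):
                for j in range(i + 1, len(parts)):
                    assert not set(parts[i]) & set(parts[j])
            tr, va, te = plan.split(0)
            assert not set(tr) & set(va) and not set(tr) & set(te) \
                and not set(va) & set(te)

    def test_small_class_falls_back_unstratified(self):
        labels = np.array([0] * 95 + [1] * 5)
        with pytest.warns(UserWarning):
            plan = make_fold_plan(100, labels, seed=0)
        assert not plan.stratified


class TestNestedCV:
    def test_oracle_classifier_perfect(self):
        ep = _epochs(seed=1)
        plan = make_fold_plan(300, ep.labels, seed=1)
        rep = nested_cv(ep, None, plan, classifier_factory=OracleClassifier)
        assert rep.val_mean == 1.0 and rep.test_mean == 1.0
        assert np.all(rep.confusion_normalized == np.eye(5))

    def test_constant_classifier_at_chance(self):
        ep = _epochs(seed=2)
        plan = make_fold_plan(300, ep.labels, seed=2)
        rep = nested_cv(ep, None, plan,
                        classifier_factory=lambda: ConstantClassifier(2))
        assert rep.val_mean == pytest.approx(0.2, abs=1e-9)
        nz = np.nonzero(rep.confusion_counts)
        assert set(nz[1].tolist()) == {2}

    def test_rows_of_normalized_confusion_sum_to_one(self):
        ep = _epochs(seed=3)
        plan = make_fold_plan(300, ep.labels, seed=3)
        rep = nested_cv(ep, None, plan, classifier_factory=OracleClassifier)
        np.testing.assert_allclose(rep.confusion_normalized.sum(axis=1), 1.0,
                                   atol=1e-9)


class TestAggregateConfusion:
    def test_hand_checked_sum(self):
        counts, norm, flags = aggregate_confusion(
            [np.array([[2, 0], [1, 1]]), np.array([[0, 2], [1, 1]])])
        np.testing.assert_array_equal(counts, [[2, 2], [2, 2]])
        np.testing.assert_array_equal(norm, [[0.5, 0.5], [0.5, 0.5]])
        assert flags == []

    def test_identity_matrices(self):
        counts, norm, _ = aggregate_confusion([np.eye(3, dtype=int)] * 2)
        np.testing.assert_array_equal(norm, np.eye(3))

    def test_renormalization_idempotent(self):
        m = np.array([[3, 1], [2, 2]])
        _, norm1, _ = aggregate_confusion([m])
        _, norm2, _ = aggregate_confusion([norm1 * 4])
        np.testing.assert_allclose(norm1, norm2)

    def test_empty_row_flagged(self):
        counts, norm, flags = aggregate_confusion(
            [np.array([[0, 0], [1, 3]])])
        assert flags == [0]
        np.testing.assert_array_equal(norm[0], [0.0, 0.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_confusion([np.eye(2), np.eye(3)])


class TestBinomialChance:
    def test_four_class_n300_reproduces_33_percent(self):
        th = binomial_chance_threshold(300, 4, 0.001)
        assert round(th) == 33

    def test_five_class_theoretical_limit(self):
        # large-n limit approaches 100/K
        th = binomial_chance_threshold(10**6, 5, 0.01)
        assert th == pytest.approx(20.0, abs=0.2)

    def test_against_monte_carlo_quantile(self, rng):
        n, k, alpha = 50, 2, 0.05
        draws = rng.binomial(n, 1 / k, size=10**6)
        # smallest count whose exceedance probability is < alpha
        mc = 0
        for c in range(n + 1):
            if (draws >= c).mean() < alpha:
                mc = c
                break
        assert binomial_chance_threshold(n, k, alpha) \
            == pytest.approx(100.0 * mc / n, abs=100.0 / n)

    def test_monotonicity(self):
        ths_n = [binomial_chance_threshold(n, 5, 0.01)
                 for n in (50, 100, 300, 1000)]
        assert all(a >= b for a, b in zip(ths_n, ths_n[1:]))
        ths_a = [binomial_chance_threshold(300, 5, a)
                 for a in (0.001, 0.01, 0.05)]
        assert all(a >= b for a, b in zip(ths_a, ths_a[1:]))

    def test_invalid_alpha_rejected(self):
        for alpha in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                binomial_chance_threshold(100, 5, alpha)


class TestEmpiricalChance:
    def test_mean_of_fold_accuracies(self):
        rep = EvalReport(fold_val_accuracy=[0.3, 0.35, 0.34])
        assert empirical_chance(rep) == 33.0

    def test_single_fold(self):
        rep = EvalReport(fold_val_accuracy=[0.25])
        assert empirical_chance(rep) == 25.0


class TestPairedAccuracyTest:
    def test_identical_samples_degenerate(self):
        a = np.array([0.5, 0.6, 0.7])
        with pytest.raises(DegenerateTestError):
            paired_accuracy_test(a, a)

    def test_closed_form_oracle(self, rng):
        d = np.array([1.0, 1.0, 1.0, 1.0]) + 1e-6 * rng.standard_normal(4)
        b = rng.standard_normal(4)
        a = b + d
        t, p = paired_accuracy_test(a, b)
        # textbook formula on the differences
        t_want = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_want = 2 * stats.t.sf(abs(t_want), len(d) - 1)
        assert t == pytest.approx(t_want, rel=1e-9)
        assert p == pytest.approx(p_want, rel=1e-9)
        assert t > 100 and p < 1e-4

    def test_type_one_error_calibration(self, rng):
        # 10^4 null replicates, alpha=0.05: rejection rate in [0.04, 0.06]
        n_rep, n = 10**4, 10
        a = rng.standard_normal((n_rep, n))
        b = rng.standard_normal((n_rep, n))
        res = stats.ttest_rel(a, b, axis=1)
        rate = float(np.mean(res.pvalue < 0.05))
        assert 0.04 <= rate <= 0.06


class TestLOSO:
    def test_requires_three_sessions(self):
        ep = _epochs(n=50, k=5)
        with pytest.raises(ValueError):
            loso_cv([ep, ep], None, classifier_factory=OracleClassifier)

    def test_channel_mismatch_rejected(self):
        a = _epochs(n=50, k=5, n_ch=2)
        b = _epochs(n=50, k=5, n_ch=3)
        with pytest.raises(ValueError):
            loso_cv([a, b, a], None, classifier_factory=OracleClassifier)

    def test_identical_subjects_transfer_perfectly(self):
        sessions = [_epochs(n=100, k=5, seed=s) for s in (1, 2, 3)]
        out = loso_cv(sessions, None, classifier_factory=OracleClassifier)
        assert out["held_out_mean"] == 1.0
        assert out["pooled_val_mean"] == 1.0

    def test_subject_specific_geometry_dissociation(self):
        """Shared geometry transfers across subjects; per-subject geometry
        keeps pooled-validation accuracy high while held-out accuracy drops
        to chance."""
        from megdecode.lfcnn import LFCNNConfig
        from megdecode.preprocess import standardize_epochs
        from megdecode.synth import SessionConfig, simulate_epochs

        def sessions(mix_seeds):
            out = []
            for s, ms in enumerate(mix_seeds):
                # both task classes share the alpha band: discrimination is
                # purely spatial, so it hinges on the mixing geometry
                cfg = SessionConfig(n_channels=16, sfreq=125, n_classes=3,
                                    trials_per_class=20,
                                    class_source_bands=(None, (10.0, 4.0),
                                                        (10.0, 4.0)),
                                    snr=10.0, seed=100 + s,
                                    accel_mode="control")
                sess = simulate_epochs(cfg)
                if ms is not None:
                    # re-mix through a subject-specific matrix
                    from megdecode.synth import make_mixing_matrix
                    mix = make_mixing_matrix(16, 3, 2.0, seed=ms)
                    data = sess.epochs.data - np.einsum(
                        "cs,nst->nct", sess.mixing, sess.source_traces)
                    data += np.einsum("cs,nst->nct", mix, sess.source_traces)
                    sess.epochs.data = data
                out.append(standardize_epochs(sess.epochs))
            return out

        mcfg = LFCNNConfig(n_latent=4, kernel_len=16, pool_window=16,
                           pool_stride=8, batch_size=30, steps_per_epoch=5,
                           max_epochs=10, patience=3, seed=0)
        shared = loso_cv(sessions([None, None, None]), mcfg, seed=0)
        chance = binomial_chance_threshold(60, 3, 0.05) / 100.0
        assert shared["held_out_mean"] > chance
        private = loso_cv(sessions([11, 22, 33]), mcfg, seed=0)
        assert private["pooled_val_mean"] > chance
        assert private["held_out_mean"] < shared["held_out_mean"]


class TestRotatingHoldout:
    def test_rotating_test_fold_disjoint_and_rotates(self):
        ep = _epochs(n=100, k=5, seed=9)
        plan = make_fold_plan(100, ep.labels, seed=9, holdout="rotating")
        seen_tests = []
        for i in range(plan.n_folds):
            tr, va, te = plan.split(i)
            assert not set(va) & set(te)
            assert not set(tr) & set(va) and not set(tr) & set(te)
            assert len(tr) + len(va) + len(te) == 100
            seen_tests.append(tuple(te))
        assert len(set(seen_tests)) == plan.n_folds

    def test_invalid_mode_rejected(self):
        ep = _epochs(n=50, k=5)
        with pytest.raises(ValueError):
            make_fold_plan(50, ep.labels, seed=0, holdout="bogus")


def test_exclude_rest_class_four_class_variant():
    ep = _epochs(n=100, k=5, seed=4)
    four = ep.exclude_class(0)
    assert four.n_classes == 4
    assert four.n_trials == 80
    assert set(np.unique(four.labels)) == {0, 1, 2, 3}
    assert len(four.class_names) == 4
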