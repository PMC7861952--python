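import numpy as np
import pytest

import emgfuse as ef
from emgfuse.augmentation import (
    AugmentationSpec,
    augment_training_set,
    fit_class_gaussian,
    generate_virtual_samples,
    infer_discrete_columns,
)
from emgfuse.containers import FeatureTable


def _table(X, y, discrete=None):
    return FeatureTable(X=np.asarray(X, float), y=np.asarray(y), discrete=discrete)


class TestFitClassGaussian:
    def test_two_point_sample_mean_and_sd(self):
        t = _table([[2.0], [4.0]], [0, 0])
        # need a second class for a meaningful classifier table, but the fit
        # itself is per class; add one
        t = _table([[2.0], [4.0], [7.0], [9.0]], [0, 0, 1, 1])
        m = fit_class_gaussian(t)
        i = m.class_index(0)
        assert m.mu[i, 0] == pytest.approx(3.0)
        assert m.eta[i, 0] == pytest.approx(np.sqrt(2.0))  # ddof=1

    def test_discrete_feature_gets_mode_and_zero_eta(self):
        t = _table(
            [[1.0, 3.0], [2.0, 3.0], [3.0, 3.0], [5.0, 4.0], [6.0, 4.0]],
            [0, 0, 0, 1, 1],
            discrete=np.array([False, True]),
        )
        m = fit_class_gaussian(t)
        assert m.eta[m.class_index(0), 1] == 0.0
        assert m.mu[m.class_index(0), 1] == 3.0
        assert m.mu[m.class_index(1), 1] == 4.0

    def test_eta_nonnegative_for_any_fit(self):
        rng = np.random.default_rng(0)
        t = _table(rng.standard_normal((30, 4)), rng.integers(0, 3, 30))
        m = fit_class_gaussian(t)
        assert np.all(m.eta >= 0.0)
        assert m.continuous_count + int(m.is_discrete.sum()) == m.feature_count

    def test_single_row_class_raises_instructive_error(self):
        t = _table([[1.0], [2.0], [3.0]], [0, 0, 1])
        with pytest.raises(ValueError, match="discrete"):
            fit_class_gaussian(t)


class TestGenerateVirtualSamples:
    def test_degenerate_model_emits_identical_rows(self):
        t = _table([[3.0, 5.0]] * 3 + [[1.0, 1.0]] * 3, [0] * 3 + [1] * 3)
        m = fit_class_gaussian(t)
        v = generate_virtual_samples(m, 0, 5, seed=1)
        assert v.n_rows == 5
        np.testing.assert_array_equal(v.X, np.tile([3.0, 5.0], (5, 1)))
        assert np.all(v.y == 0)

    def test_moment_recovery_at_large_m(self):
        # mu=0, eta=1, m=100000 -> sample mean within 3/sqrt(m) of mu and
        # sample sd within the same band of eta
        t = _table([[0.0], [1.0], [-1.0], [10.0], [11.0], [9.0]], [0, 0, 0, 1, 1, 1])
        m_model = fit_class_gaussian(t)
        i = m_model.class_index(0)
        m_model.mu[i, 0], m_model.eta[i, 0] = 0.0, 1.0
        m = 100_000
        v = generate_virtual_samples(m_model, 0, m, seed=2)
        tol = 3.0 / np.sqrt(m)
        assert abs(v.X[:, 0].mean() - 0.0) < tol
        assert abs(v.X[:, 0].std(ddof=1) - 1.0) < 2 * tol

    def test_zero_draws_keep_schema(self):
        t = _table([[1.0, 2.0]] * 2 + [[3.0, 4.0]] * 2, [0, 0, 1, 1])
        v = generate_virtual_samples(fit_class_gaussian(t), 1, 0, seed=0)
        assert v.n_rows == 0
        assert v.n_features == 2
        assert v.feature_names == t.feature_names

    def test_unknown_class_rejected(self):
        t = _table([[1.0]] * 2 + [[2.0]] * 2, [0, 0, 1, 1])
        with pytest.raises(KeyError):
            generate_virtual_samples(fit_class_gaussian(t), 9, 3)

    def test_deterministic_given_seed(self):
        t = _table(np.random.default_rng(1).standard_normal((10, 3)), [0] * 5 + [1] * 5)
        m = fit_class_gaussian(t)
        a = generate_virtual_samples(m, 0, 50, seed=9)
        b = generate_virtual_samples(m, 0, 50, seed=9)
        np.testing.assert_array_equal(a.X, b.X)


class TestAugmentTrainingSet:
    def test_replication_factor_sets_row_count(self):
        rng = np.random.default_rng(2)
        t = _table(rng.standard_normal((12, 3)), [0] * 4 + [1] * 4 + [2] * 4)
        out = augment_training_set(t, AugmentationSpec(replication_factor=1000, seed=0))
        assert out.n_rows == 12 + 12 * 1000

    def test_zero_factor_is_identity(self):
        rng = np.random.default_rng(3)
        t = _table(rng.standard_normal((8, 2)), [0] * 4 + [1] * 4)
        out = augment_training_set(t, AugmentationSpec(replication_factor=0))
        np.testing.assert_array_equal(out.X, t.X)
        np.testing.assert_array_equal(out.y, t.y)

    def test_per_class_virtual_counts_scale_with_original_counts(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 3 + [1] * 5 + [2] * 4)
        t = _table(rng.standard_normal((12, 2)), y)
        R = 7
        out = augment_training_set(t, AugmentationSpec(replication_factor=R, seed=1))
        for c, n_c in zip(*np.unique(y, return_counts=True)):
            assert int((out.y == c).sum()) == n_c * (1 + R)

    def test_augmentation_preserves_label_set(self, toy_table):
        out = augment_training_set(toy_table, AugmentationSpec(replication_factor=5, seed=2))
        np.testing.assert_array_equal(np.unique(out.y), np.unique(toy_table.y))

    def test_discrete_values_never_leave_the_class_mode(self, toy_table):
        out = augment_training_set(toy_table, AugmentationSpec(replication_factor=20, seed=3))
        j = int(np.nonzero(toy_table.discrete)[0][0])
        for c in toy_table.classes:
            seen = set(np.unique(toy_table.X[toy_table.y == c, j]))
            virt = out.X[(out.y == c) & (out.trial_id == -1), j]
            assert set(np.unique(virt)) <= seen

    def test_virtual_rows_marked_with_sentinel_trial_id(self, toy_table):
        out = augment_training_set(toy_table, AugmentationSpec(replication_factor=2, seed=4))
        n_virtual = int((out.trial_id == -1).sum())
        assert n_virtual == 2 * toy_table.n_rows


class TestDiscreteInference:
    def test_integral_low_cardinality_columns_flagged(self):
        rng = np.random.default_rng(5)
        X = np.column_stack(
            [rng.standard_normal(50), rng.integers(0, 3, 50).astype(float), np.arange(50, dtype=float)]
        )
        flags = infer_discrete_columns(X)
        np.testing.assert_array_equal(flags, [False, True, False])
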