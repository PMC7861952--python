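import itertools

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix

import emgfuse as ef
from emgfuse.classify_fuse import (
    ELM_ACTIVATIONS,
    FusionTable,
    SvmSpec,
    fuse_predict,
    per_class_accuracy,
    select_best_variant,
    select_local_classifiers,
    train_elm,
    train_softmax,
    train_svm,
)


def _blobs(n_per_class=30, n_classes=2, d=4, sep=10.0, seed=0):
    t = ef.make_toy_multiclass(n_per_class, n_classes, d, separation=sep, seed=seed)
    return t.X, t.y


class TestElm:
    def test_xor_interpolated_with_enough_hidden_units(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        m = train_elm(X, y, hidden=10, activation="logistic", ridge=0.0, seed=0)
        np.testing.assert_array_equal(m.predict(X), y)

    @pytest.mark.parametrize("activation", ["sine", "radbas", "logistic"])
    def test_interpolation_when_hidden_exceeds_samples(self, activation):
        # H >= N with ridge=0: analytic activations interpolate the labels
        rng = np.random.default_rng(hash(activation) % 2**31)
        for trial in range(10):
            X = rng.standard_normal((12, 3))
            y = rng.integers(0, 3, 12)
            if np.unique(y).size < 2:
                continue
            m = train_elm(X, y, hidden=40, activation=activation, ridge=0.0, seed=trial)
            assert np.mean(m.predict(X) == y) == 1.0

    def test_solution_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 4))
        y = rng.integers(0, 3, 20)
        m = train_elm(X, y, hidden=15, activation="sine", ridge=0.0, seed=3)
        # independent recomputation from the model's fixed random layer
        G = np.sin(X @ m.W.T + m.b)
        T = (y[:, None] == m.classes[None, :]).astype(float)
        np.testing.assert_allclose(m.B, np.linalg.pinv(G) @ T, atol=1e-8)

    def test_separated_blobs_generalize(self):
        # standardized inputs, as the pipeline always feeds the bank
        X, y = _blobs(seed=2)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        tr, te = idx[:40], idx[40:]
        m = train_elm(X[tr], y[tr], hidden=50, activation="sine", seed=1)
        assert np.mean(m.predict(X[te]) == y[te]) >= 0.95

    def test_deterministic_given_seed(self):
        X, y = _blobs(seed=3)
        a = train_elm(X, y, hidden=20, activation="radbas", seed=7)
        b = train_elm(X, y, hidden=20, activation="radbas", seed=7)
        np.testing.assert_array_equal(a.B, b.B)

    def test_scores_row_normalize(self):
        X, y = _blobs(seed=4)
        m = train_elm(X, y, hidden=20, seed=0)
        s = m.predict_scores(X)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_hidden_rejected(self):
        X, y = _blobs()
        with pytest.raises(ValueError):
            train_elm(X, y, hidden=0)


class TestSvm:
    def test_linear_kernel_separates_separable_data(self):
        X, y = _blobs(seed=5)
        m = train_svm(X, y, SvmSpec("linear"))
        assert np.mean(m.predict(X) == y) == 1.0

    def test_concentric_circles_need_the_gaussian_kernel(self):
        rng = np.random.default_rng(6)
        n = 100
        r = np.concatenate([rng.uniform(0, 1, n), rng.uniform(3, 4, n)])
        th = rng.uniform(0, 2 * np.pi, 2 * n)
        X = np.column_stack([r * np.cos(th), r * np.sin(th)])
        y = np.repeat([0, 1], n)
        lin = train_svm(X, y, SvmSpec("linear"))
        fine = train_svm(X, y, SvmSpec("fine-gaussian"))
        assert np.mean(lin.predict(X) == y) <= 0.7
        assert np.mean(fine.predict(X) == y) >= 0.9

    def test_quadratic_kernel_solves_conic_separation(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-2, 2, (150, 2))
        y = (X[:, 0] ** 2 + X[:, 1] ** 2 > 1.5).astype(int)
        m = train_svm(X, y, SvmSpec("quadratic"))
        assert np.mean(m.predict(X) == y) >= 0.97

    def test_scores_row_normalize(self):
        X, y = _blobs(n_classes=3, seed=8)
        m = train_svm(X, y, SvmSpec("medium-gaussian"))
        np.testing.assert_allclose(m.predict_scores(X).sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((5, 2)), np.zeros(5))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            SvmSpec("sigmoid")


class TestSoftmax:
    def test_probabilities_sum_to_one(self):
        X, y = _blobs(n_classes=3, seed=9)
        m = train_softmax(X, y)
        np.testing.assert_allclose(m.predict_scores(X).sum(axis=1), 1.0, atol=1e-9)

    def test_separable_blobs_classified(self):
        X, y = _blobs(seed=10)
        m = train_softmax(X, y)
        assert np.mean(m.predict(X) == y) >= 0.95

    def test_extreme_l2_shrinks_to_uniform(self):
        X, y = _blobs(seed=11)
        m = train_softmax(X, y, l2=1e12)
        p = m.predict_scores(X)
        np.testing.assert_allclose(p, 0.5, atol=1e-3)


class _Stub:
    def __init__(self, preds):
        self._p = np.asarray(preds)

    def predict(self, X):
        return self._p


class TestSelection:
    def test_highest_validation_accuracy_wins(self):
        yv = np.array([0, 0, 1, 1, 1])
        cands = [
            ("a", _Stub([0, 1, 0, 1, 1])),  # 0.6
            ("b", _Stub([0, 0, 1, 1, 0])),  # 0.8
            ("c", _Stub([1, 0, 1, 1, 0])),  # 0.6
        ]
        vid, _, acc = select_best_variant(cands, np.zeros((5, 1)), yv)
        assert (vid, acc) == ("b", 0.8)

    def test_single_candidate_chosen(self):
        vid, _, _ = select_best_variant([("only", _Stub([0, 1]))], np.zeros((2, 1)), np.array([0, 1]))
        assert vid == "only"

    def test_ties_go_to_first_declared(self):
        yv = np.array([0, 1])
        cands = [("a", _Stub([0, 1])), ("b", _Stub([0, 1]))]
        vid, _, _ = select_best_variant(cands, np.zeros((2, 1)), yv)
        assert vid == "a"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_best_variant([], np.zeros((1, 1)), np.array([0]))


class TestPerClassAccuracy:
    def test_hand_counted_example(self):
        acc = per_class_accuracy(np.array(["a", "b", "b", "b"]), np.array(["a", "a", "b", "b"]))
        assert acc == {"a": 0.5, "b": 1.0}

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0])
        assert per_class_accuracy(y, y) == {0: 1.0, 1: 1.0, 2: 1.0}

    def test_matches_confusion_matrix_diagonal_oracle(self):
        rng = np.random.default_rng(12)
        truth = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        acc = per_class_accuracy(pred, truth)
        cm = confusion_matrix(truth, pred, labels=np.arange(4))
        for c in range(4):
            assert acc[c] == pytest.approx(cm[c, c] / cm[c].sum())


class TestFusion:
    def test_each_class_goes_to_its_best_family(self):
        tables = {"ELM": {1: 0.9, 2: 0.5}, "SVM": {1: 0.6, 2: 0.8}}
        f = select_local_classifiers(tables)
        assert f.assignment[1][0] == "ELM"
        assert f.assignment[2][0] == "SVM"

    def test_single_family_owns_everything(self):
        f = select_local_classifiers({"SL": {0: 0.4, 1: 0.2}})
        assert {fam for fam, _ in f.assignment.values()} == {"SL"}

    def test_all_equal_accuracies_respect_priority_order(self):
        tables = {"SL": {0: 0.5, 1: 0.5}, "SVM": {0: 0.5, 1: 0.5}, "ELM": {0: 0.5, 1: 0.5}}
        f = select_local_classifiers(tables)
        assert {fam for fam, _ in f.assignment.values()} == {"ELM"}

    def test_exhaustive_argmax_on_accuracy_grid(self):
        # every 2-family x 2-class table over a coarse accuracy grid
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        for a0, a1, b0, b1 in itertools.product(grid, repeat=4):
            tables = {"ELM": {0: a0, 1: a1}, "SVM": {0: b0, 1: b1}}
            f = select_local_classifiers(tables)
            for c, (fam, _) in f.assignment.items():
                assert tables[fam][c] == max(tables["ELM"][c], tables["SVM"][c])
                if tables["ELM"][c] == tables["SVM"][c]:
                    assert fam == "ELM"  # tie priority

    def test_mismatched_class_sets_rejected(self):
        with pytest.raises(ValueError):
            select_local_classifiers({"ELM": {0: 0.5}, "SVM": {0: 0.5, 1: 0.5}})

    def test_misassigned_table_rejected(self):
        with pytest.raises(ValueError):
            FusionTable(
                assignment={0: ("SVM", "linear")},
                selection_accuracies={"ELM": {0: 0.9}, "SVM": {0: 0.1}},
            )


class TestFusePredict:
    def test_reduces_to_single_classifier_when_it_owns_all_classes(self):
        rng = np.random.default_rng(13)
        scores = rng.dirichlet(np.ones(3), size=20)
        other = rng.dirichlet(np.ones(3), size=20)
        f = select_local_classifiers(
            {"ELM": {0: 0.9, 1: 0.9, 2: 0.9}, "SVM": {0: 0.1, 1: 0.1, 2: 0.1}}
        )
        pred = fuse_predict(f, {"ELM": scores, "SVM": other}, classes=[0, 1, 2])
        np.testing.assert_array_equal(pred, np.argmax(scores, axis=1))

    def test_two_class_gating_matches_hand_enumeration(self):
        # ELM owns class 0, SVM owns class 1: fused score vector is
        # (elm[:,0], svm[:,1]); enumerate the four orderings
        f = select_local_classifiers({"ELM": {0: 0.9, 1: 0.2}, "SVM": {0: 0.1, 1: 0.8}})
        elm = np.array([[0.9, 0.1], [0.9, 0.1], [0.2, 0.8], [0.2, 0.8]])
        svm = np.array([[0.7, 0.3], [0.1, 0.9], [0.7, 0.3], [0.1, 0.9]])
        pred = fuse_predict(f, {"ELM": elm, "SVM": svm}, classes=[0, 1])
        # fused rows: (0.9,0.3)->0, (0.9,0.9) tie -> lowest index 0,
        # (0.2,0.3)->1, (0.2,0.9)->1
        np.testing.assert_array_equal(pred, [0, 0, 1, 1])

    def test_missing_family_scores_rejected(self):
        f = select_local_classifiers({"ELM": {0: 0.9, 1: 0.2}, "SVM": {0: 0.1, 1: 0.8}})
        with pytest.raises(ValueError, match="missing"):
            fuse_predict(f, {"ELM": np.ones((2, 2)) / 2}, classes=[0, 1])

    def test_fused_training_accuracy_at_least_min_of_families(self):
        X, y = _blobs(n_classes=3, n_per_class=20, sep=3.0, seed=14)
        elm = train_elm(X, y, hidden=30, seed=0)
        svm = train_svm(X, y, SvmSpec("linear"))
        sl = train_softmax(X, y)
        models = {"ELM": elm, "SVM": svm, "SL": sl}
        tables = {k: per_class_accuracy(m.predict(X), y) for k, m in models.items()}
        f = select_local_classifiers(tables)
        pred = fuse_predict(f, {k: m.predict_scores(X) for k, m in models.items()}, classes=[0, 1, 2])
        fused_acc = np.mean(pred == y)
        assert fused_acc >= min(np.mean(m.predict(X) == y) for m in models.values())
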