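"""The convnet, the hybrid SVM head, the feature baselines and model I/O."""

import numpy as np
import pandas as pd
import pytest

from gaitguard.features import FEATURE_NAMES
from gaitguard.models import (
    BASELINE_PRESETS,
    KNN_GRID,
    SVM_GRID,
    CnnHyper,
    classify,
    cnn_probabilities,
    decision_values,
    load_model,
    save_model,
    train_baseline,
    train_cnn,
    train_hybrid_head,
)


@pytest.fixture(scope="module")
def tiny_cnn(tiny_benchmark):
    train = tiny_benchmark.in_split("train")
    return train_cnn(train.windows, train.multiclass_labels(), CnnHyper(seed=7)), train


class TestCnn:
    def test_probabilities_normalized(self, tiny_cnn, tiny_benchmark):
        model, _ = tiny_cnn
        probs = cnn_probabilities(model, tiny_benchmark.windows[:50])
        assert probs.shape == (50, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_training_loss_decreases(self, tiny_cnn):
        model, _ = tiny_cnn
        assert model.history[-1] < model.history[0]

    def test_seen_test_accuracy(self, tiny_cnn, tiny_benchmark):
        model, _ = tiny_cnn
        test = tiny_benchmark.in_split("test")
        pred = model.predict(test.windows)
        assert (pred == test.multiclass_labels()).mean() >= 0.95

    def test_deterministic_weights_under_seed(self, tiny_benchmark):
        train = tiny_benchmark.in_split("train")
        hyper = CnnHyper(seed=3, epochs=2)
        a = train_cnn(train.windows, train.multiclass_labels(), hyper)
        b = train_cnn(train.windows, train.multiclass_labels(), hyper)
        for k in a.net.params:
            np.testing.assert_array_equal(a.net.params[k], b.net.params[k])

    def test_missing_class_rejected(self, tiny_benchmark):
        train = tiny_benchmark.in_split("train")
        y = train.multiclass_labels()
        keep = y != 2
        with pytest.raises(ValueError, match=r"\[2\]"):
            train_cnn(train.windows[keep], y[keep], CnnHyper(seed=0, epochs=1))

    def test_wrong_shape_rejected(self, tiny_cnn):
        model, _ = tiny_cnn
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((4, 100, 6)))


class TestHybridHead:
    def _one_hot_data(self):
        p = np.vstack([np.tile([0.98, 0.01, 0.01], (40, 1)),
                       np.tile([0.01, 0.98, 0.01], (20, 1)),
                       np.tile([0.01, 0.01, 0.98], (20, 1))])
        y = np.array([1] * 40 + [0] * 40)
        return p, y

    def test_separable_vectors_perfectly_fit_by_preset(self):
        p, y = self._one_hot_data()
        svm, _ = train_hybrid_head(p, y, mode="preset")
        assert (svm.predict(p) == y).all()

    def test_preset_uses_tuned_operating_point(self):
        p, y = self._one_hot_data()
        svm, results = train_hybrid_head(p, y, mode="preset")
        assert results is None
        assert svm.kernel == "poly" and svm.C == 1 and svm.gamma == 0.1

    def test_grid_search_explores_48_configurations(self):
        p, y = self._one_hot_data()
        svm, results = train_hybrid_head(p, y, mode="search")
        assert len(results) == 3 * 4 * 4
        assert (svm.predict(p) == y).all()

    def test_single_class_rejected(self):
        p, _ = self._one_hot_data()
        with pytest.raises(ValueError):
            train_hybrid_head(p, np.ones(len(p), dtype=int))


class TestBaselines:
    def _features(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 174)) + y[:, None] * 3.0
        return pd.DataFrame(X, columns=list(FEATURE_NAMES)), y

    def test_knn_preset_score_is_neighbor_fraction(self):
        # 3 duplicated points per class: each training point's 3-NN are its
        # own class, so scores are exactly 0 or 1 and predictions reproduce y
        X = pd.DataFrame(np.repeat([[0.0] * 174, [5.0] * 174], 3, axis=0),
                         columns=list(FEATURE_NAMES))
        y = np.array([0, 0, 0, 1, 1, 1])
        model = train_baseline(X, y, "knn")
        scores = decision_values(model, X)
        np.testing.assert_allclose(scores, y.astype(float))

    def test_rf_preset_has_200_trees_and_unit_votes(self):
        X, y = self._features()
        model = train_baseline(X, y, "rf")
        assert len(model.estimator.estimators_) == 200
        assert model.estimator.max_depth == 7
        scores = decision_values(model, X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_svm_preset_hyperparameters(self):
        X, y = self._features()
        model = train_baseline(X, y, "svm")
        svc = model.estimator.named_steps["svc"]
        assert svc.kernel == "poly" and svc.C == 0.1 and svc.gamma == 1

    def test_knn_grid_explores_10_configurations(self):
        X, y = self._features(n=80)
        model = train_baseline(X, y, "knn", mode="search")
        assert len(model.search_results) == 5 * 2
        assert len(KNN_GRID["n_neighbors"]) * len(KNN_GRID["weights"]) == 10

    def test_svm_grid_is_48_points(self):
        assert (len(SVM_GRID["kernel"]) * len(SVM_GRID["C"])
                * len(SVM_GRID["gamma"]) == 48)

    def test_schema_mismatch_rejected(self):
        X, y = self._features()
        model = train_baseline(X, y, "rf")
        wrong = X.rename(columns={FEATURE_NAMES[0]: "bogus"})
        with pytest.raises(ValueError, match="schema"):
            decision_values(model, wrong)

    def test_presets_match_tuned_values(self):
        assert BASELINE_PRESETS["knn"] == {"n_neighbors": 3, "weights": "uniform"}
        assert BASELINE_PRESETS["rf"]["n_estimators"] == 200


class TestClassify:
    class _Stub:
        family = "hybrid"

        def decision_values(self, scores):
            return np.asarray(scores, dtype=float)

    def test_sign_threshold_on_scores(self):
        labels = classify(self._Stub(), [-1.0, 1.0], threshold=0.0)
        np.testing.assert_array_equal(labels, [0, 1])

    def test_threshold_above_max_rejects_all(self):
        labels = classify(self._Stub(), [-1.0, 1.0], threshold=2.0)
        np.testing.assert_array_equal(labels, [0, 0])

    def test_threshold_below_min_accepts_all(self):
        labels = classify(self._Stub(), [-1.0, 1.0], threshold=-np.inf)
        np.testing.assert_array_equal(labels, [1, 1])

    def test_monotone_in_threshold(self, rng):
        scores = rng.normal(size=200)
        stub = self._Stub()
        prev = classify(stub, scores, threshold=-3.0)
        for t in np.linspace(-3, 3, 25):
            cur = classify(stub, scores, threshold=t)
            assert not np.any(cur > prev)  # raising t never flips 0 -> 1
            prev = cur


class TestSerialization:
    def test_hybrid_round_trip(self, tiny_hybrid, tiny_benchmark, tmp_path):
        batch = tiny_benchmark.windows[:40]
        save_model(tiny_hybrid, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        np.testing.assert_allclose(decision_values(back, batch),
                                   decision_values(tiny_hybrid, batch), atol=1e-12)

    def test_baseline_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 30)
        X = pd.DataFrame(rng.normal(size=(60, 174)) + y[:, None],
                         columns=list(FEATURE_NAMES))
        model = train_baseline(X, y, "rf")
        save_model(model, tmp_path / "rf")
        back = load_model(tmp_path / "rf")
        np.testing.assert_array_equal(decision_values(back, X),
                                      decision_values(model, X))
        assert back.schema == model.schema
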