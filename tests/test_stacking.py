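"""Stacked generalization: out-of-fold hygiene, meta-features, prediction."""

import numpy as np
import pytest

from talsrx import learners, stacking
from talsrx.stacking import (
    StackConfig,
    fit_stack,
    make_folds,
    oof_meta_features,
    stack_predict_proba,
)


class FrequencyProbe:
    """Probe learner predicting its training set's class distribution for
    every input — makes out-of-fold rows exactly computable."""

    def fit(self, X, y):
        self.dist = np.bincount(y, minlength=11) / len(y)
        return self

    def predict_proba(self, X):
        return np.tile(self.dist, (len(X), 1))


class MemorizingProbe:
    """Probe that outputs 1 for samples it saw at fit time, 0 otherwise —
    any leakage of the held-out fold into training is directly visible."""

    def fit(self, X, y):
        self.seen = {row.tobytes() for row in np.asarray(X)}
        return self

    def predict_proba(self, X):
        out = np.zeros((len(X), 11))
        out[:, 0] = [1.0 if row.tobytes() in self.seen else 0.0 for row in X]
        return out


def probe_fitter(cls):
    return lambda X, y: cls().fit(X, y)


@pytest.fixture(scope="module")
def small_xy():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 6))
    y = np.repeat([0, 5, 10], 20)
    return X, y


class TestFolds:
    def test_partition_is_disjoint_exhaustive_near_equal(self):
        folds = make_folds(53, 5, seed=0)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.sum() == 53
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic(self):
        np.testing.assert_array_equal(make_folds(40, 5, 7), make_folds(40, 5, 7))


class TestOofMetaFeatures:
    def test_shape_is_n_by_22_for_two_learners(self, small_xy):
        X, y = small_xy
        Z, folds = oof_meta_features(
            X, y, [probe_fitter(FrequencyProbe), probe_fitter(FrequencyProbe)], k=5, seed=0
        )
        assert Z.shape == (60, 22)
        assert folds.shape == (60,)

    def test_frequency_probe_rows_equal_training_fold_distribution(self, small_xy):
        X, y = small_xy
        Z, folds = oof_meta_features(X, y, [probe_fitter(FrequencyProbe)], k=5, seed=0)
        for j in range(5):
            held = folds == j
            expected = np.bincount(y[~held], minlength=11) / (~held).sum()
            np.testing.assert_allclose(Z[held], np.tile(expected, (held.sum(), 1)))

    def test_no_leakage_with_memorizing_probe(self, small_xy):
        X, y = small_xy
        Z, folds = oof_meta_features(X, y, [probe_fitter(MemorizingProbe)], k=5, seed=1)
        # every row was predicted by a model that never saw that sample
        assert (Z[:, 0] == 0.0).all()

    def test_row_permutation_leaves_row_multiset_unchanged(self, small_xy):
        X, y = small_xy
        Z1, folds = oof_meta_features(X, y, [probe_fitter(FrequencyProbe)], k=5, seed=3)
        perm = np.random.default_rng(0).permutation(len(y))
        # same partition of the same samples, presented in permuted order
        Z2, _ = oof_meta_features(
            X[perm], y[perm], [probe_fitter(FrequencyProbe)], k=5,
            fold_assignments=folds[perm],
        )
        np.testing.assert_allclose(np.sort(Z1[perm], axis=0), np.sort(Z2, axis=0))

    def test_k_below_two_rejected(self, small_xy):
        X, y = small_xy
        with pytest.raises(ValueError):
            oof_meta_features(X, y, [probe_fitter(FrequencyProbe)], k=1)

    def test_fold_missing_class_pads_zero_probability(self):
        # class 10 has a single sample; the model predicting its own fold was
        # trained without class 10 and must give it exactly zero probability
        rng = np.random.default_rng(0)
        X = rng.normal(size=(21, 4))
        y = np.array([0] * 10 + [5] * 10 + [10])
        fitter = lambda Xa, ya: learners.fit_learner("rf", Xa, ya, rng=0)
        Z, folds = oof_meta_features(X, y, [fitter], k=5, seed=2)
        lone_fold = folds[20]
        assert (Z[folds == lone_fold, 10] == 0.0).all()


@pytest.fixture(scope="module")
def fitted(three_class_data):
    X, y = three_class_data
    cfg = StackConfig(budgets={"svm": 4, "rf": 3, "xgb": 4})
    return X, y, fit_stack(X, y, cfg, seed=0)


class TestFitStack:

    def test_base_learner_kinds_and_meta(self, fitted):
        _, _, model = fitted
        assert set(model.base_models) == {"svm", "rf"}
        assert set(model.tuned_params) == {"svm", "rf", "xgb"}
        assert model.meta_model is not None

    def test_fold_assignments_partition(self, fitted):
        X, y, model = fitted
        sizes = np.bincount(model.fold_assignments, minlength=5)
        assert sizes.sum() == len(y)
        assert sizes.max() - sizes.min() <= 1

    def test_training_data_predicted_above_chance(self, fitted):
        X, y, model = fitted
        assert np.mean(model.predict(X) == y) > 1 / 11

    def test_predict_proba_row_stochastic(self, fitted):
        X, _, model = fitted
        p = model.predict_proba(X[:7])
        assert p.shape == (7, 11)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_single_row_input(self, fitted):
        X, _, model = fitted
        assert model.predict_proba(X[:1]).shape == (1, 11)

    def test_column_mismatch_rejected(self, fitted):
        _, _, model = fitted
        with pytest.raises(ValueError, match="feature columns"):
            stack_predict_proba(model, np.zeros((3, 50)))

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 4))
        y = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="2 classes"):
            fit_stack(X, y, seed=0)

    def test_reproducible_under_seed(self, three_class_data):
        X, y = three_class_data
        cfg = StackConfig(
            fixed_params={
                "svm": learners.SVMParams(),
                "rf": learners.RFParams(n_estimators=30),
                "xgb": learners.XGBParams(n_estimators=40),
            }
        )
        p1 = fit_stack(X, y, cfg, seed=5).predict_proba(X[:10])
        p2 = fit_stack(X, y, cfg, seed=5).predict_proba(X[:10])
        np.testing.assert_array_equal(p1, p2)


def test_stack_separates_extreme_classes_perfectly(extreme_plates):
    X_train, y_train, X_test, y_test = extreme_plates
    cfg = StackConfig(
        fixed_params={
            "svm": learners.SVMParams(),
            "rf": learners.RFParams(n_estimators=50),
            "xgb": learners.XGBParams(n_estimators=50),
        }
    )
    model = fit_stack(X_train, y_train, cfg, seed=0)
    assert np.mean(model.predict(X_test) == y_test) == 1.0
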