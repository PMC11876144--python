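"""Two-layer stacked generalization.

Layer one: a PSO-tuned SVM and a random-search-tuned random forest produce
5-fold out-of-fold class-probability predictions on the training set.  The
held-out predictions are horizontally spliced into the meta-feature matrix
``Z = [Z_svm | Z_rf]`` (22 columns for 11 classes), so every row of ``Z`` was
produced by models that never saw that sample.  Layer two: a
Bayesian-optimization-tuned XGBoost meta-learner is fitted on ``(Z, y)``.

At inference the base models (refitted on the full training set) predict
probabilities, which are spliced and passed to the meta-learner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold

from . import learners
from .plate import N_CLASSES, N_FEATURES

logger = logging.getLogger(__name__)

#: Base-learner order in the meta-feature splice: SVM block then RF block.
BASE_KINDS = ("svm", "rf")


@dataclass
class StackConfig:
    k_folds: int = 5
    budgets: dict = field(default_factory=lambda: {"svm": 12, "rf": 8, "xgb": 10})
    #: pre-tuned parameters per kind; kinds not listed are tuned here
    fixed_params: dict = field(default_factory=dict)
    n_features: int = N_FEATURES


@dataclass
class StackModel:
    base_models: dict          # kind -> ClassProbModel, fitted on full train
    meta_model: object         # ClassProbModel over meta-features
    fold_assignments: np.ndarray
    tuned_params: dict         # kind -> typed params (incl. "xgb" meta)
    cv_scores: dict
    n_features: int = N_FEATURES

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return stack_predict_proba(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random k-way partition into near-equal disjoint folds; returns the
    per-sample fold index (0..k-1)."""
    assignments = np.empty(n, dtype=int)
    for fold_i, (_, held) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n))
    ):
        assignments[held] = fold_i
    return assignments


def oof_meta_features(
    X: np.ndarray,
    y: np.ndarray,
    base_fitters: Sequence[Callable[[np.ndarray, np.ndarray], object]],
    k: int = 5,
    seed: int = 0,
    fold_assignments: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold class-probability meta-features.

    For each fold, each base fitter is trained on the other ``k - 1`` folds
    and predicts class probabilities on the held-out fold; per-sample blocks
    are concatenated across fitters in order.  A class missing from the
    training folds contributes a zero probability column for those rows
    (the fitted wrappers pad absent classes).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    n = X.shape[0]
    if fold_assignments is None:
        fold_assignments = make_folds(n, k, seed)
    Z = np.zeros((n, len(base_fitters) * N_CLASSES))
    for fold_i in range(k):
        held = fold_assignments == fold_i
        rest = ~held
        for m, fitter in enumerate(base_fitters):
            model = fitter(X[rest], y[rest])
            block = slice(m * N_CLASSES, (m + 1) * N_CLASSES)
            Z[held, block] = model.predict_proba(X[held])
    return Z, fold_assignments


def fit_stack(
    X: np.ndarray, y: np.ndarray, config: StackConfig | None = None, seed: int = 0
) -> StackModel:
    """Tune, build out-of-fold meta-features, fit the meta-learner, refit bases.

    Hyperparameters are tuned once on the full training set (5-fold CV
    objective) before the out-of-fold construction; the final base models are
    refitted on all of the training data for inference.
    """
    config = config or StackConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("stacking needs at least 2 classes in the training set")

    tuned, cv_scores = {}, {}
    for kind in BASE_KINDS:
        if kind in config.fixed_params:
            tuned[kind] = config.fixed_params[kind]
            cv_scores[kind] = float("nan")
        else:
            tuned[kind], cv_scores[kind], _ = learners.tune_learner(
                kind, X, y, budget=config.budgets[kind], rng=seed
            )
            logger.info("tuned %s: %s (cv acc %.4f)", kind, tuned[kind], cv_scores[kind])

    fitters = [
        (lambda Xa, ya, _k=kind: learners.fit_learner(_k, Xa, ya, tuned[_k], rng=seed))
        for kind in BASE_KINDS
    ]
    Z, fold_assignments = oof_meta_features(
        X, y, fitters, k=config.k_folds, seed=seed
    )

    if "xgb" in config.fixed_params:
        tuned["xgb"] = config.fixed_params["xgb"]
        cv_scores["xgb"] = float("nan")
    else:
        tuned["xgb"], cv_scores["xgb"], _ = learners.tune_learner(
            "xgb", Z, y, budget=config.budgets["xgb"], rng=seed
        )
        logger.info("tuned meta xgb: %s (cv acc %.4f)", tuned["xgb"], cv_scores["xgb"])
    meta = learners.fit_xgb(Z, y, tuned["xgb"], rng=seed)

    base_models = {
        kind: learners.fit_learner(kind, X, y, tuned[kind], rng=seed)
        for kind in BASE_KINDS
    }
    return StackModel(
        base_models=base_models,
        meta_model=meta,
        fold_assignments=fold_assignments,
        tuned_params=tuned,
        cv_scores=cv_scores,
        n_features=X.shape[1],
    )


def stack_predict_proba(model: StackModel, X: np.ndarray) -> np.ndarray:
    """Base models -> spliced probabilities -> meta-learner probabilities."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got "
            f"{X.shape[1] if X.ndim == 2 else X.shape}"
        )
    Z = np.hstack(
        [model.base_models[kind].predict_proba(X) for kind in BASE_KINDS]
    )
    return model.meta_model.predict_proba(Z)
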