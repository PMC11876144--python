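"""The three tuned classical learners: random forest, RBF-kernel SVM, XGBoost.

Each is wrapped so that ``predict_proba`` always returns an 11-column
row-stochastic matrix over the score classes, with zero probability for
classes absent from training.  The canonical optimizer pairing follows the
method's design: random search for the forest (RS-RF), particle swarm for the
SVM (PSO-SVM), Bayesian optimization for XGBoost (BO-XGBoost).

The forest's literal absolute-majority vote rule (predict a class only when
it takes more than half of all tree votes, otherwise reject) is exposed as a
standalone operation; the stacking pipeline consumes vote *fractions* as
probabilities instead, since a meta-learner needs dense features.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .optimize import (
    OptResult,
    Param,
    Params,
    SearchSpace,
    bayes_optimize,
    pso_optimize,
    random_search,
)
from .plate import N_CLASSES

logger = logging.getLogger(__name__)

#: Sentinel returned by the absolute-majority vote when no class clears 50%.
REJECT = "reject"


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters (defaults: the tuned configuration)."""

    n_estimators: int = 202
    max_depth: int = 34
    min_samples_split: int = 5
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.min_samples_leaf > self.min_samples_split:
            raise ValueError("min_samples_leaf must be <= min_samples_split")


@dataclass(frozen=True)
class SVMParams:
    """Support-vector-machine hyperparameters (defaults: the tuned configuration)."""

    C: float = 695.65
    kernel: str = "rbf"
    gamma: float = 0.0089

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class XGBParams:
    """Gradient-boosting hyperparameters (defaults: the tuned configuration)."""

    colsample_bytree: float = 0.87
    learning_rate: float = 0.29
    max_depth: int = 7
    n_estimators: int = 139
    subsample: float = 0.83

    def __post_init__(self) -> None:
        for name in ("colsample_bytree", "learning_rate", "subsample"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        for name in ("max_depth", "n_estimators"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


def rf_majority_vote(tree_outputs: Sequence, threshold: float = 0.5):
    """Absolute-majority vote over per-tree class votes.

    ``tree_outputs`` is one vote (class label) per tree.  Returns the class
    whose vote count exceeds ``threshold`` of all votes, else :data:`REJECT`.
    """
    votes = list(tree_outputs)
    if not votes:
        raise ValueError("empty vote set")
    classes, counts = np.unique(np.asarray(votes), return_counts=True)
    top = int(np.argmax(counts))
    if counts[top] > threshold * len(votes):
        return classes[top].item()
    return REJECT


class ClassProbModel:
    """Wrap a fitted sklearn-style classifier to the fixed 11-class space.

    Classes absent from training get probability exactly 0; a single-class
    training set yields a degenerate constant classifier (logged).
    """

    def __init__(self, inner, present_classes: np.ndarray, n_classes: int = N_CLASSES):
        self.inner = inner
        self.present_classes = np.asarray(present_classes, dtype=int)
        self.n_classes = n_classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], self.n_classes))
        if self.inner is None:  # degenerate single-class model
            out[:, self.present_classes[0]] = 1.0
            return out
        p = self.inner.predict_proba(X)
        out[:, self.present_classes] = p
        # guard against numerical drift in backends
        out /= out.sum(axis=1, keepdims=True)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.inner is not None and not hasattr(self.inner, "predict_proba"):
            # uncalibrated SVM during tuning: class prediction needs no Platt scaling
            return self.present_classes[self.inner.predict(np.asarray(X, dtype=float))]
        return np.argmax(self.predict_proba(X), axis=1)


def _wrap_fit(factory: Callable[[np.ndarray], object], X, y) -> ClassProbModel:
    """Fit with remapped consecutive labels; handle the single-class corner."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    present = np.unique(y)
    if present.size == 1:
        logger.warning(
            "single-class training set (class %d): degenerate constant model",
            present[0],
        )
        return ClassProbModel(None, present)
    remap = {c: i for i, c in enumerate(present)}
    y_consec = np.array([remap[v] for v in y])
    inner = factory(y_consec)
    import warnings

    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecation chatter for SVC(probability=True)
        warnings.simplefilter("ignore", FutureWarning)
        inner.fit(X, y_consec)
    return ClassProbModel(inner, present)


def fit_rf(X, y, params: RFParams = RFParams(), rng: int = 0) -> ClassProbModel:
    """Bagged forest of unpruned-ish trees with random feature subsets per split."""
    return _wrap_fit(
        lambda _: RandomForestClassifier(
            n_estimators=params.n_estimators,
            max_depth=params.max_depth,
            min_samples_split=params.min_samples_split,
            min_samples_leaf=params.min_samples_leaf,
            random_state=rng,
            n_jobs=1,
        ),
        X,
        y,
    )


def fit_svm(
    X, y, params: SVMParams = SVMParams(), rng: int = 0, probability: bool = True
) -> ClassProbModel:
    """RBF-kernel SVM, one-vs-one multi-class, pairwise-coupled sigmoid
    calibration for probability outputs."""
    return _wrap_fit(
        lambda _: SVC(
            C=params.C,
            kernel=params.kernel,
            gamma=params.gamma,
            probability=probability,
            random_state=rng,
        ),
        X,
        y,
    )


def fit_xgb(X, y, params: XGBParams = XGBParams(), rng: int = 0) -> ClassProbModel:
    """Gradient-boosted trees minimizing softmax cross-entropy plus the
    tree-complexity regularizer."""
    return _wrap_fit(
        lambda y_consec: XGBClassifier(
            n_estimators=params.n_estimators,
            max_depth=params.max_depth,
            learning_rate=params.learning_rate,
            subsample=params.subsample,
            colsample_bytree=params.colsample_bytree,
            objective="multi:softprob",
            num_class=int(np.unique(y_consec).size),
            tree_method="hist",
            random_state=rng,
            n_jobs=1,
            verbosity=0,
        ),
        X,
        y,
    )


# -- default search spaces (bracket the tuned Table-of-defaults values) ----

def default_space(kind: str) -> SearchSpace:
    if kind == "rf":
        return SearchSpace(
            [
                Param("n_estimators", "integer", 50, 400),
                Param("max_depth", "integer", 5, 40),
                Param("min_samples_split", "integer", 2, 10),
                Param("min_samples_leaf", "integer", 1, 5),
            ]
        )
    if kind == "svm":
        return SearchSpace(
            [
                Param("C", "real", 1.0, 1000.0, scale="log"),
                Param("gamma", "real", 1e-4, 1.0, scale="log"),
            ]
        )
    if kind == "xgb":
        return SearchSpace(
            [
                Param("max_depth", "integer", 3, 10),
                Param("learning_rate", "real", 0.01, 0.3, scale="log"),
                Param("n_estimators", "integer", 50, 300),
                Param("subsample", "real", 0.5, 1.0),
                Param("colsample_bytree", "real", 0.5, 1.0),
            ]
        )
    raise ValueError(f"unknown learner kind {kind!r}")


_PARAM_CLS = {"rf": RFParams, "svm": SVMParams, "xgb": XGBParams}
_FITTERS = {"rf": fit_rf, "svm": fit_svm, "xgb": fit_xgb}
#: Canonical learner/optimizer pairing: RS-RF, PSO-SVM, BO-XGBoost.
DEFAULT_OPTIMIZER = {"rf": "random", "svm": "pso", "xgb": "bayes"}


def make_params(kind: str, params: Params):
    """Build the typed parameter object for a learner from a plain dict
    (clamping min_samples_leaf <= min_samples_split for the forest)."""
    if kind == "rf" and "min_samples_leaf" in params:
        params = dict(params)
        params["min_samples_leaf"] = min(
            params["min_samples_leaf"], params.get("min_samples_split", 10)
        )
    return _PARAM_CLS[kind](**params)


def fit_learner(kind: str, X, y, params=None, rng: int = 0, **kw) -> ClassProbModel:
    if params is None:
        params = _PARAM_CLS[kind]()
    return _FITTERS[kind](X, y, params, rng=rng, **kw)


def cv_accuracy_objective(
    kind: str, X, y, n_splits: int = 5, seed: int = 0
) -> Callable[[Params], float]:
    """Mean k-fold cross-validated accuracy of a learner configuration.

    Folds are fixed once (stratified, seeded) so every configuration sees the
    same partition.  The SVM is evaluated without probability calibration —
    ``predict`` does not depend on it and skipping Platt scaling halves cost.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))

    def objective(raw: Params) -> float:
        params = make_params(kind, raw)
        accs = []
        for fold_i, (tr, va) in enumerate(folds):
            kw = {"probability": False} if kind == "svm" else {}
            model = fit_learner(kind, X[tr], y[tr], params, rng=seed, **kw)
            accs.append(float(np.mean(model.predict(X[va]) == y[va])))
        return float(np.mean(accs))

    return objective


def tune_learner(
    kind: str,
    X,
    y,
    optimizer_kind: str | None = None,
    budget: int = 20,
    rng: int = 0,
    space: SearchSpace | None = None,
    n_splits: int = 5,
) -> tuple[object, float, OptResult]:
    """Search a learner's hyperparameter space, maximizing mean CV accuracy.

    Returns ``(typed_params, cv_score, OptResult)``.  The optimizer defaults
    to the canonical pairing (rf: random search, svm: PSO, xgb: Bayesian).
    """
    if kind not in _PARAM_CLS:
        raise ValueError(f"unknown learner kind {kind!r}")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    optimizer_kind = optimizer_kind or DEFAULT_OPTIMIZER[kind]
    space = space or default_space(kind)
    objective = cv_accuracy_objective(kind, X, y, n_splits=n_splits, seed=rng)

    if optimizer_kind == "random":
        result = random_search(objective, space, n_iter=budget, rng=rng)
    elif optimizer_kind == "pso":
        n_particles = max(2, min(6, budget))
        n_iter = max(0, budget // n_particles - 1)
        result = pso_optimize(
            objective, space, n_particles=n_particles, n_iter=n_iter, rng=rng
        )
    elif optimizer_kind == "bayes":
        n_init = max(2, min(5, budget - 1)) if budget > 2 else 2
        n_iter = max(0, budget - n_init)
        result = bayes_optimize(objective, space, n_init=n_init, n_iter=n_iter, rng=rng)
    else:
        raise ValueError(f"unknown optimizer kind {optimizer_kind!r}")
    return make_params(kind, result.best_params), result.best_objective, result
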