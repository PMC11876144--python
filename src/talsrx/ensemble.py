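"""Soft-voting fusion of the stacking, ANN-LSTM and Transformer branches.

The final typing-effect score is the argmax of a weighted average of the
three branches' class-probability matrices.  Voting weights live on a 0.05
grid in [0, 1] and are chosen by exhaustive grid search on an internal
validation split; the tuned defaults are (stacking, ANN-LSTM, Transformer) =
(0.95, 0.55, 0.25).  Weights are normalized by their sum inside the vote so
the fused matrix stays row-stochastic; rescaling all weights by a positive
constant never changes a predicted score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import deep, stacking
from .metrics import overall_accuracy
from .plate import N_FEATURES, decode_label

logger = logging.getLogger(__name__)

#: Branch order used throughout: stacking, ANN-LSTM, Transformer.
BRANCHES = ("stacking", "ann_lstm", "transformer")
DEFAULT_WEIGHTS = (0.95, 0.55, 0.25)


@dataclass
class EnsembleConfig:
    stack: stacking.StackConfig = field(default_factory=stacking.StackConfig)
    ann_lstm: deep.AnnLstmConfig = field(default_factory=deep.AnnLstmConfig)
    transformer: deep.TransformerConfig = field(default_factory=deep.TransformerConfig)
    grid_step: float = 0.05
    validation_fraction: float = 0.15
    #: refit all branches on the full training set after the weight search
    refit: bool = True


@dataclass
class EnsembleModel:
    stack: stacking.StackModel
    ann_lstm: deep.AnnLstmModel
    transformer: deep.TransformerModel
    weights: tuple[float, float, float]
    n_features: int = N_FEATURES

    def branch_probas(self, X: np.ndarray) -> list[np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} feature columns")
        return [
            self.stack.predict_proba(X),
            self.ann_lstm.predict_proba(X),
            self.transformer.predict_proba(X),
        ]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return soft_vote(self.branch_probas(X), self.weights)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def soft_vote(prob_matrices: list[np.ndarray], weights) -> np.ndarray:
    """Weighted average of probability matrices, normalized by the weight sum."""
    weights = np.asarray(weights, dtype=float)
    if len(prob_matrices) != weights.size:
        raise ValueError("one weight per probability matrix required")
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    mats = [np.asarray(m, dtype=float) for m in prob_matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("probability matrices must share a shape")
    fused = sum(w * m for w, m in zip(weights, mats)) / weights.sum()
    return fused


def weight_lattice(n_models: int, grid_step: float):
    """All weight tuples on {0, step, ..., 1}^n except all-zero, in
    lexicographic order."""
    n_steps = round(1.0 / grid_step)
    if abs(n_steps * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step {grid_step} must divide 1 evenly")
    levels = [round(i * grid_step, 10) for i in range(n_steps + 1)]
    for combo in itertools.product(levels, repeat=n_models):
        if any(w > 0 for w in combo):
            yield combo


def grid_search_weights(
    prob_matrices: list[np.ndarray],
    y_validation: np.ndarray,
    grid_step: float = 0.05,
) -> tuple[float, ...]:
    """Exhaustive search over the weight lattice maximizing fused accuracy.

    Ties are broken by the earliest lattice point in lexicographic order.
    """
    y = np.asarray(y_validation, dtype=int)
    if y.size == 0:
        raise ValueError("empty validation set")
    mats = [np.asarray(m, dtype=float) for m in prob_matrices]
    best_w, best_acc = None, -1.0
    for combo in weight_lattice(len(mats), grid_step):
        w = np.asarray(combo)
        fused = sum(wi * m for wi, m in zip(w, mats))
        acc = overall_accuracy(y, np.argmax(fused, axis=1))
        if acc > best_acc:
            best_w, best_acc = combo, acc
    logger.info("grid search selected weights %s (val acc %.4f)", best_w, best_acc)
    return best_w


def _fit_branches(X, y, config: EnsembleConfig, seed: int):
    stack = stacking.fit_stack(X, y, config.stack, seed=seed)
    ann = deep.fit_ann_lstm(X, y, config.ann_lstm, seed=seed + 1)
    trans = deep.fit_transformer(X, y, config.transformer, seed=seed + 2)
    return stack, ann, trans


def fit_tal_srx(
    X: np.ndarray, y: np.ndarray, config: EnsembleConfig | None = None, seed: int = 0
) -> EnsembleModel:
    """Train the full fusion model.

    A stratified validation split (default 15%) is carved from the training
    set; the three branches are fitted on the remainder, the voting weights
    are grid-searched on the validation probabilities, and (by default) the
    branches are then refitted on all of the training data with the chosen
    weights.
    """
    config = config or EnsembleConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    stratify = y if (counts[counts > 0] >= 2).all() else None
    idx_fit, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=config.validation_fraction,
        random_state=seed,
        stratify=stratify,
    )
    stack, ann, trans = _fit_branches(X[idx_fit], y[idx_fit], config, seed)
    val_probas = [
        stack.predict_proba(X[idx_val]),
        ann.predict_proba(X[idx_val]),
        trans.predict_proba(X[idx_val]),
    ]
    weights = grid_search_weights(val_probas, y[idx_val], config.grid_step)
    if config.refit:
        stack, ann, trans = _fit_branches(X, y, config, seed)
    return EnsembleModel(
        stack=stack, ann_lstm=ann, transformer=trans, weights=weights,
        n_features=X.shape[1],
    )


def predict_scores(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Typing-effect scores in {0, 10, ..., 100} for each plate row."""
    classes = model.predict(X)
    return np.array([decode_label(c) for c in classes])
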