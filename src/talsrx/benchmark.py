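"""End-to-end synthetic benchmark.

Generates a labeled synthetic plate dataset, trains every model variant —
the three tuned single learners (RS-RF, PSO-SVM, BO-XGBoost), the two neural
branches, the stacking model, and the soft-vote combinations up to the full
three-branch fusion — and evaluates all of them on a common held-out test
split.  The report has one row per model with accuracy, macro precision /
recall / F1, Cohen's kappa and macro one-vs-rest AUC.

Protocol: a validation carve (default 15%) is taken from the training split;
every model is fitted on the remaining fit portion, soft-vote weights are
grid-searched on the validation probabilities, and all rows are evaluated on
the untouched test split.  Single-branch probability matrices are computed
once and reused by every vote combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from . import deep, ensemble, learners, metrics, stacking, synth
from .plate import SCORES, split_dataset

logger = logging.getLogger(__name__)

MODEL_ROWS = (
    "RS-RF",
    "PSO-SVM",
    "BO-XGBoost",
    "ANN-LSTM",
    "Transformer",
    "Stacking",
    "ANN-LSTM+Transformer",
    "Stacking+ANN-LSTM",
    "Stacking+Transformer",
    "TAL-SRX",
)


@dataclass
class RunConfig:
    """Resolved configuration of one benchmark run."""

    seed: int = 0
    train_per_class: int = 100
    test_per_class: int = 30
    class_scores: tuple = SCORES
    jitter: float = 0.2
    validation_fraction: float = 0.15
    grid_step: float = 0.05
    budgets: dict = field(default_factory=lambda: {"rf": 4, "svm": 8, "xgb": 6})
    #: scaled-down training lengths for the neural branches (full default: 500)
    ann_epochs: int = 150
    transformer_epochs: int = 15
    deep_batch_size: int = 64

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_scores"] = list(self.class_scores)
        return d


def _seeds(root: int, n: int) -> list[int]:
    """Derive independent component seeds (< 2**31) from one root seed."""
    return [int(s) for s in
            np.random.SeedSequence(root).generate_state(n) % (2**31 - 1)]


def run_benchmark(config: RunConfig | None = None) -> dict:
    """Run the full model comparison; returns a JSON-serializable report."""
    config = config or RunConfig()
    (seed_data, seed_split, seed_val, seed_rf, seed_svm, seed_xgb,
     seed_ann, seed_trans, seed_stack) = _seeds(config.seed, 9)

    per_class = config.train_per_class + config.test_per_class
    data = synth.generate_dataset(
        {s: per_class for s in config.class_scores}, seed_data, jitter=config.jitter
    )
    train, test = split_dataset(
        data, train_frac=config.train_per_class / per_class, rng_seed=seed_split
    )
    X_train, y_train = train.feature_matrix(), train.class_indices()
    X_test, y_test = test.feature_matrix(), test.class_indices()

    idx_fit, idx_val = train_test_split(
        np.arange(len(y_train)),
        test_size=config.validation_fraction,
        random_state=seed_val,
        stratify=y_train,
    )
    X_fit, y_fit = X_train[idx_fit], y_train[idx_fit]
    X_val, y_val = X_train[idx_val], y_train[idx_val]

    val_probas: dict[str, np.ndarray] = {}
    test_probas: dict[str, np.ndarray] = {}
    tuned: dict[str, object] = {}

    # --- tuned single learners ---------------------------------------
    for kind, row, seed in (("rf", "RS-RF", seed_rf), ("svm", "PSO-SVM", seed_svm),
                            ("xgb", "BO-XGBoost", seed_xgb)):
        params, cv_score, _ = learners.tune_learner(
            kind, X_fit, y_fit, budget=config.budgets[kind], rng=seed
        )
        tuned[kind] = params
        logger.info("%s tuned: %s (cv acc %.4f)", row, params, cv_score)
        model = learners.fit_learner(kind, X_fit, y_fit, params, rng=seed)
        val_probas[row] = model.predict_proba(X_val)
        test_probas[row] = model.predict_proba(X_test)

    # --- neural branches ----------------------------------------------
    ann_cfg = deep.AnnLstmConfig(
        epochs=config.ann_epochs, batch_size=config.deep_batch_size
    )
    ann = deep.fit_ann_lstm(X_fit, y_fit, ann_cfg, seed=seed_ann)
    val_probas["ANN-LSTM"] = ann.predict_proba(X_val)
    test_probas["ANN-LSTM"] = ann.predict_proba(X_test)

    trans_cfg = deep.TransformerConfig(
        epochs=config.transformer_epochs, batch_size=config.deep_batch_size
    )
    trans = deep.fit_transformer(X_fit, y_fit, trans_cfg, seed=seed_trans)
    val_probas["Transformer"] = trans.predict_proba(X_val)
    test_probas["Transformer"] = trans.predict_proba(X_test)

    # --- stacking (reuses the tuned RF / SVM configurations) ----------
    stack_cfg = stacking.StackConfig(
        budgets=config.budgets,
        fixed_params={"rf": tuned["rf"], "svm": tuned["svm"]},
    )
    stack = stacking.fit_stack(X_fit, y_fit, stack_cfg, seed=seed_stack)
    val_probas["Stacking"] = stack.predict_proba(X_val)
    test_probas["Stacking"] = stack.predict_proba(X_test)

    # --- soft-vote combinations ---------------------------------------
    combos = {
        "ANN-LSTM+Transformer": ("ANN-LSTM", "Transformer"),
        "Stacking+ANN-LSTM": ("Stacking", "ANN-LSTM"),
        "Stacking+Transformer": ("Stacking", "Transformer"),
        "TAL-SRX": ("Stacking", "ANN-LSTM", "Transformer"),
    }
    fused_weights = {}
    for row, members in combos.items():
        w = ensemble.grid_search_weights(
            [val_probas[m] for m in members], y_val, grid_step=config.grid_step
        )
        fused_weights[row] = w
        test_probas[row] = ensemble.soft_vote([test_probas[m] for m in members], w)

    # --- common evaluation --------------------------------------------
    rows = {}
    for row in MODEL_ROWS:
        P = test_probas[row]
        report = metrics.evaluate_predictions(y_test, np.argmax(P, axis=1), P)
        rows[row] = report.summary()

    return {
        "config": config.to_dict(),
        "n_train": int(len(y_train)),
        "n_test": int(len(y_test)),
        "weights": {k: list(v) for k, v in fused_weights.items()},
        "models": rows,
    }
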