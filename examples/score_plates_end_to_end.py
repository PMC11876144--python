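"""Train the full fusion scorer and assign 0-100 scores to new plates.

Fits the three branches (stacking, ANN-LSTM, Transformer) on a small
synthetic training set, grid-searches the soft-voting weights on an internal
validation split, then scores held-out plates and compares with their true
rubric classes.  Neural epochs are reduced here so the example runs in a
couple of minutes; production defaults train for 500 epochs.
"""

import numpy as np

from talsrx import generate_dataset, predict_scores, split_dataset
from talsrx.deep import AnnLstmConfig, TransformerConfig
from talsrx.ensemble import EnsembleConfig, fit_tal_srx
from talsrx.metrics import evaluate_predictions
from talsrx.stacking import StackConfig

data = generate_dataset({100: 40, 60: 40, 20: 40}, rng=1)
train, test = split_dataset(data, train_frac=0.84, rng_seed=1)

config = EnsembleConfig(
    stack=StackConfig(budgets={"svm": 4, "rf": 3, "xgb": 4}),
    ann_lstm=AnnLstmConfig(epochs=80),
    transformer=TransformerConfig(epochs=8),
    refit=False,
)
model = fit_tal_srx(
    train.feature_matrix(), train.class_indices(), config, seed=0
)
print(f"soft-voting weights (stacking, ann_lstm, transformer): {model.weights}")

X_test = test.feature_matrix()
scores = predict_scores(model, X_test)
truth = test.scores()
print(f"predicted: {scores[:10]}")
print(f"true:      {truth[:10]}")

P = model.predict_proba(X_test)
report = evaluate_predictions(test.class_indices(), np.argmax(P, axis=1), P)
print(
    f"\naccuracy {report.accuracy:.3f}, kappa {report.kappa:.3f} "
    f"({report.kappa_label}), macro AUC {report.macro_auc:.3f}"
)
print("scores are the argmax of the weighted average of the three branches'")
print("class probabilities, mapped back to the 0-100 rubric scale")
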