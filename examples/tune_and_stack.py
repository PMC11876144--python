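"""Tune the base learners and fit the two-layer stacked model.

Builds a small 3-class synthetic dataset, tunes the SVM with particle swarm
and the forest with random search, assembles 5-fold out-of-fold meta-features
and fits the XGBoost meta-learner, then scores a held-out split.
"""

import numpy as np

from talsrx import generate_dataset, split_dataset
from talsrx.stacking import StackConfig, fit_stack

data = generate_dataset({100: 40, 50: 40, 0: 40}, rng=0)
train, test = split_dataset(data, train_frac=0.84, rng_seed=0)

config = StackConfig(budgets={"svm": 6, "rf": 4, "xgb": 5})
model = fit_stack(train.feature_matrix(), train.class_indices(), config, seed=0)

print("tuned hyperparameters:")
for kind, params in model.tuned_params.items():
    print(f"  {kind}: {params}")

X_test, y_test = test.feature_matrix(), test.class_indices()
acc = np.mean(model.predict(X_test) == y_test)
print(f"\nheld-out accuracy on {len(y_test)} plates: {acc:.3f}")
print("(base SVM and RF probabilities are spliced into 22 meta-features;")
print(" the XGBoost meta-learner maps those to the 11 score classes)")
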