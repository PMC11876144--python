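"""The evaluation suite on a worked example.

Shows every metric the package computes on a small hand-checkable confusion
structure: per-class and macro precision/recall/F1, the TP/(TP+FP+FN) ratio,
Cohen's kappa with its agreement band, one-vs-rest macro AUC, per-sample
score errors and the score-band histograms.
"""

import numpy as np

from talsrx.metrics import (
    band_histogram,
    cohen_kappa,
    confusion,
    error_vector,
    kappa_band,
    prf_macro,
)

# a binary worked example: 5 true positives-class samples, 5 negatives
y_true = np.array([0] * 5 + [1] * 5)
y_pred = np.array([0, 0, 0, 0, 1, 0, 0, 1, 1, 1])
cm = confusion(y_true, y_pred, n_classes=2)
print("confusion matrix:\n", cm)

res = prf_macro(cm)
pc = res["per_class"]
print(f"class-0 precision {pc['precision'][0]:.4f} (= 4/6)")
print(f"class-0 recall    {pc['recall'][0]:.4f} (= 4/5)")
print(f"class-0 F1        {pc['f1'][0]:.4f}")
print(f"class-0 TP/(TP+FP+FN) {pc['tp_over_tp_fp_fn'][0]:.4f} (= 4/7)")

k = cohen_kappa(cm)
print(f"kappa {k:.2f} -> {kappa_band(k)!r}")

# score-scale errors: each class index maps to a 0-100 band
true_scores = np.array([100, 100, 90, 50, 0])
pred_scores = np.array([100, 90, 90, 70, 0])
print("per-sample |error| in score units:", error_vector(true_scores, pred_scores))
print("true-score histogram:", {k: v for k, v in band_histogram(true_scores).items() if v})
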