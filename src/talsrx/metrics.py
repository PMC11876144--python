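"""Multi-class evaluation suite for typing-effect scoring.

Implements the standard per-class precision / recall / F1 with macro
averaging, the per-class ratio TP / (TP + FP + FN) (a Jaccard-like quantity
reported separately under its own name — it cannot equal overall accuracy and
both are exposed), Cohen's kappa with the conventional agreement bands,
one-vs-rest ROC AUC by the rank statistic, per-sample absolute score errors
and score-band histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .plate import N_CLASSES, SCORES, decode_label, validate_score

logger = logging.getLogger(__name__)

KAPPA_BANDS = (
    (0.81, "almost perfect agreement"),
    (0.61, "significant agreement"),
    (0.41, "moderate agreement"),
    (0.21, "fair agreement"),
    (0.00, "very low agreement"),
)
KAPPA_NO_AGREEMENT = "no agreement"


def confusion(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Confusion matrix: rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def overall_accuracy(y_true, y_pred) -> float:
    """Fraction of exactly correct predictions (trace(cm) / total)."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    return float(np.mean(y_true == np.asarray(y_pred)))


def prf_macro(cm: np.ndarray) -> dict:
    """Per-class precision, recall, F1 and TP/(TP+FP+FN), with macro means.

    Macro averages are unweighted means over classes present in the truth
    (non-zero row sums); a class with a zero denominator contributes 0 to its
    own metric (logged).
    """
    cm = np.asarray(cm)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp

    def safe(num, den, name):
        out = np.zeros_like(num)
        ok = den > 0
        if (~ok).any():
            logger.debug("%s: zero denominator for classes %s", name, np.where(~ok)[0])
        out[ok] = num[ok] / den[ok]
        return out

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    f1 = safe(2 * precision * recall, precision + recall, "f1")
    jaccard = safe(tp, tp + fp + fn, "tp_ratio")

    present = cm.sum(axis=1) > 0
    return {
        "per_class": {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "tp_over_tp_fp_fn": jaccard,
        },
        "macro": {
            "precision": float(precision[present].mean()),
            "recall": float(recall[present].mean()),
            "f1": float(f1[present].mean()),
            "tp_over_tp_fp_fn": float(jaccard[present].mean()),
        },
        "present": present,
    }


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e)."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if np.isclose(p_e, 1.0):
        raise ZeroDivisionError("kappa undefined: expected agreement p_e = 1")
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_band(kappa: float) -> str:
    """Map a kappa value to its conventional agreement label."""
    if kappa < 0:
        return KAPPA_NO_AGREEMENT
    for lo, label in KAPPA_BANDS:
        if kappa >= lo:
            return label
    return KAPPA_NO_AGREEMENT


def per_class_kappa(y_true, y_pred, n_classes: int = N_CLASSES) -> dict[int, float | None]:
    """One-vs-rest kappa per class; ``None`` for classes absent from both
    truth and prediction."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    out: dict[int, float | None] = {}
    for c in range(n_classes):
        t = (y_true == c).astype(int)
        p = (y_pred == c).astype(int)
        if t.sum() == 0 and p.sum() == 0:
            out[c] = None
            continue
        cm2 = confusion(t, p, n_classes=2)
        try:
            out[c] = cohen_kappa(cm2)
        except ZeroDivisionError:
            out[c] = None
    return out


def _binary_auc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) AUC with ties counted half."""
    n_pos = int(y_bin.sum())
    n_neg = y_bin.size - n_pos
    ranks = rankdata(scores)
    u = ranks[y_bin == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ovr_macro_auc(y_true, prob_matrix) -> float:
    """Macro one-vs-rest AUC over the classes present in the truth."""
    y_true = np.asarray(y_true, dtype=int)
    P = np.asarray(prob_matrix, dtype=float)
    present = np.unique(y_true)
    if present.size < 2:
        raise ValueError("AUC undefined with a single class present")
    aucs = [_binary_auc((y_true == c).astype(int), P[:, c]) for c in present]
    return float(np.mean(aucs))


def error_vector(y_true_scores, y_pred_scores) -> np.ndarray:
    """Per-sample absolute score error |true - predicted|, in score units."""
    t = np.asarray(y_true_scores, dtype=int)
    p = np.asarray(y_pred_scores, dtype=int)
    for v in np.concatenate([t, p]):
        validate_score(int(v))
    return np.abs(t - p)


def band_histogram(scores) -> dict[int, int]:
    """Sample counts per score band (0, 10, ..., 100)."""
    s = np.asarray(scores, dtype=int)
    for v in s:
        validate_score(int(v))
    return {band: int(np.sum(s == band)) for band in SCORES}


@dataclass
class EvalReport:
    """Full evaluation of score predictions against expert labels."""

    confusion_matrix: np.ndarray
    accuracy: float
    macro: dict
    per_class: dict
    kappa: float
    kappa_label: str
    per_class_kappa: dict
    macro_auc: float | None
    errors: np.ndarray
    true_histogram: dict
    pred_histogram: dict

    def summary(self) -> dict:
        """JSON-friendly headline metrics."""
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro["precision"],
            "macro_recall": self.macro["recall"],
            "macro_f1": self.macro["f1"],
            "kappa": self.kappa,
            "macro_auc": self.macro_auc,
        }


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    prob_matrix: np.ndarray | None = None,
) -> EvalReport:
    """Assemble the full report from class indices (and optional probabilities)."""
    cm = confusion(y_true, y_pred)
    prf = prf_macro(cm)
    kappa = cohen_kappa(cm)
    auc = None
    if prob_matrix is not None and np.unique(np.asarray(y_true)).size >= 2:
        auc = ovr_macro_auc(y_true, prob_matrix)
    t_scores = np.array([decode_label(c) for c in np.asarray(y_true, dtype=int)])
    p_scores = np.array([decode_label(c) for c in np.asarray(y_pred, dtype=int)])
    return EvalReport(
        confusion_matrix=cm,
        accuracy=overall_accuracy(y_true, y_pred),
        macro=prf["macro"],
        per_class=prf["per_class"],
        kappa=kappa,
        kappa_label=kappa_band(kappa),
        per_class_kappa=per_class_kappa(y_true, y_pred),
        macro_auc=auc,
        errors=error_vector(t_scores, p_scores),
        true_histogram=band_histogram(t_scores),
        pred_histogram=band_histogram(p_scores),
    )
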