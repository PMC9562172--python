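"""Multi-class evaluation metrics: accuracy, MCC, and one-vs-rest ROC AUC.

Accuracy is the trace of the confusion matrix over the sample count.  For
two classes MCC is the familiar binary correlation of predictions and
truth; for more classes the generalized covariance form is used, which
reduces exactly to the binary formula at C=2.  AUC is computed per class
one-vs-rest by trapezoidal integration of the ROC curve and macro-averaged
over the classes that have both positives and negatives.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import roc_curve


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """C x C counts, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(confusion: np.ndarray) -> float:
    confusion = np.asarray(confusion)
    n = confusion.sum()
    if confusion.size == 0 or n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / n)


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient from a confusion matrix.

    Binary problems use TP*TN - FP*FN over the geometric mean of the four
    marginal products; larger problems use the multi-class generalization
    cov(pred, true) / sqrt(cov(pred, pred) * cov(true, true)).  A zero
    denominator yields 0 by convention.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.shape[0] == 2:
        return _mcc_binary(cm)
    return _mcc_multiclass(cm)


def _mcc_binary(cm: np.ndarray) -> float:
    # rows true, cols predicted; positive class = index 1
    tp, fn = cm[1, 1], cm[1, 0]
    fp, tn = cm[0, 1], cm[0, 0]
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def _mcc_multiclass(cm: np.ndarray) -> float:
    n = cm.sum()
    t = cm.sum(axis=1)  # true-class counts
    p = cm.sum(axis=0)  # predicted-class counts
    c = np.trace(cm)
    cov_tp = c * n - t @ p
    cov_pp = n * n - p @ p
    cov_tt = n * n - t @ t
    denom = np.sqrt(cov_pp) * np.sqrt(cov_tt)
    if denom == 0:
        return 0.0
    return float(cov_tp / denom)


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    fpr, tpr, _ = roc_curve(positives, scores)
    return float(np.trapezoid(tpr, fpr))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Macro one-vs-rest AUC over classes with at least one positive and
    one negative; degenerate classes are skipped with a warning."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 2:
        raise ValueError("scores must be (N, C)")
    aucs = []
    for c in range(scores.shape[1]):
        pos = labels == c
        if pos.all() or not pos.any():
            warnings.warn(
                f"class {c} has no positives or no negatives; skipped in AUC",
                stacklevel=2,
            )
            continue
        aucs.append(_binary_auc(scores[:, c], pos))
    if not aucs:
        raise ValueError("no class with both positives and negatives; AUC undefined")
    return float(np.mean(aucs))


def per_class_counts(confusion: np.ndarray) -> list[dict]:
    """One-vs-rest TP/TN/FP/FN per class."""
    cm = np.asarray(confusion)
    n = cm.sum()
    out = []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        out.append({"TP": int(tp), "TN": int(tn), "FP": int(fp), "FN": int(fn)})
    return out


def evaluate(
    y_true: np.ndarray, probs: np.ndarray, n_classes: int
) -> dict:
    """Full metrics report: ACC, MCC, AUC, confusion matrix, per-class counts."""
    y_pred = np.asarray(probs).argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred, n_classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            auc = roc_auc(probs, y_true)
        except ValueError:
            auc = float("nan")
    return {
        "acc": accuracy(cm),
        "mcc": mcc(cm),
        "auc": auc,
        "confusion": cm,
        "per_class": per_class_counts(cm),
    }
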