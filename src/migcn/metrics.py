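"""Classifier evaluation: confusion matrix, GAA, kappa, P/R/F1, ROC/AUC.

GAA ("global average accuracy") is the overall fraction of correctly
classified test segments, trace(confusion)/n; a macro-averaged-recall
variant is exposed alongside it.  The ROC is micro-averaged one-vs-rest:
all (sample, class) indicator/score pairs are pooled and swept jointly,
with tied scores grouped at one threshold and the area taken by the
trapezoidal rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    confusion: np.ndarray  # rows = true, columns = predicted
    gaa: float
    kappa: float
    precision: float
    recall: float
    f1: float
    per_class_accuracy: np.ndarray
    macro_recall_gaa: float  # secondary accuracy variant
    roc_points: np.ndarray | None = None  # (n_thresholds, 2) fpr/tpr
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "gaa": self.gaa,
            "kappa": self.kappa,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class_accuracy": list(map(float, self.per_class_accuracy)),
            "confusion": self.confusion.tolist(),
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion_and_gaa(y_true, y_pred, n_classes: int = 4):
    """Counts matrix, overall accuracy and row-normalized per-class accuracy."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("label vectors must be non-empty and equal length")
    C = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(C, (y_true, y_pred), 1)
    gaa = float(np.trace(C)) / len(y_true)
    row = C.sum(axis=1)
    per_class = np.divide(
        np.diag(C), row, out=np.zeros(n_classes, float), where=row > 0
    )
    return C, gaa, per_class


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e) from a counts table."""
    C = np.asarray(confusion, float)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(C) / n
    p_e = float((C.sum(axis=1) * C.sum(axis=0)).sum()) / n**2
    if abs(1.0 - p_e) < 1e-12:
        logger.warning("degenerate table with p_e = 1; kappa defined as 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def macro_prf1(confusion: np.ndarray):
    """Macro-averaged precision, recall and F1; empty denominators count 0."""
    C = np.asarray(confusion, float)
    if C.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(C)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    with np.errstate(invalid="ignore"):
        prec = np.divide(tp, tp + fp, out=np.zeros_like(tp), where=(tp + fp) > 0)
        rec = np.divide(tp, tp + fn, out=np.zeros_like(tp), where=(tp + fn) > 0)
        pr = prec + rec
        f1 = np.divide(2 * prec * rec, pr, out=np.zeros_like(tp), where=pr > 0)
    if ((tp + fp) == 0).any() or ((tp + fn) == 0).any():
        logger.warning("class with empty precision/recall denominator counted as 0")
    return float(prec.mean()), float(rec.mean()), float(f1.mean())


def multiclass_roc_auc(y_true, class_probabilities):
    """Micro-averaged one-vs-rest ROC and trapezoidal AUC.

    Flattens the (sample, class) one-hot indicators against the score
    matrix and sweeps thresholds over the pooled scores, grouping ties.
    Returns ``(roc_points, auc)`` with roc_points an (m, 2) fpr/tpr array.
    """
    y_true = np.asarray(y_true, int)
    P = np.asarray(class_probabilities, float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("need at least two classes present in y_true")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1")
    n, k = P.shape
    truth = np.zeros((n, k), dtype=bool)
    truth[np.arange(n), y_true] = True
    scores = P.ravel()
    labels = truth.ravel()
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos, n_neg = labels.sum(), (~labels).sum()
    # group tied scores: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(scores)) if len(scores) > 1 else np.array([], int)
    idx = np.r_[distinct, len(scores) - 1]
    tp = np.cumsum(labels)[idx]
    fp = np.cumsum(~labels)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_predictions(
    y_true, y_pred, class_probabilities=None, n_classes: int = 4
) -> EvalReport:
    """Full report from labels, hard predictions and optional scores."""
    C, gaa, per_class = confusion_and_gaa(y_true, y_pred, n_classes)
    kappa = cohens_kappa(C)
    prec, rec, f1 = macro_prf1(C)
    present = C.sum(axis=1) > 0
    macro_recall = float(per_class[present].mean()) if present.any() else 0.0
    roc, auc = (None, None)
    if class_probabilities is not None:
        roc, auc = multiclass_roc_auc(y_true, class_probabilities)
    return EvalReport(C, gaa, kappa, prec, rec, f1, per_class, macro_recall, roc, auc)


def summary_stats(values) -> dict:
    """Median and quartiles (linear interpolation) for box-plot reporting."""
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(v.min()),
        "max": float(v.max()),
    }
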