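"""Evaluation utilities: ROC/AUC, precision-recall, and relative AUC drop."""

from __future__ import annotations

import numpy as np


class EvaluationError(ValueError):
    pass


def _to_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == "deleterious").astype(int)
    return arr.astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney; ties count 1/2).

    ``labels`` may be 0/1 or the strings benign/deleterious; higher scores
    should indicate the positive (deleterious) class.
    """
    from sklearn.metrics import roc_auc_score

    y = _to_binary(labels)
    if len(y) != len(np.asarray(scores)):
        raise EvaluationError("scores and labels differ in length")
    if y.min() == y.max():
        raise EvaluationError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def precision_recall(scores, labels):
    """Step-curve precision/recall at every unique threshold (no interpolation).

    Returns ``(precision, recall, thresholds)`` as produced by scikit-learn's
    step-wise computation.
    """
    from sklearn.metrics import precision_recall_curve

    y = _to_binary(labels)
    return precision_recall_curve(y, np.asarray(scores, dtype=float))


def average_precision(scores, labels) -> float:
    from sklearn.metrics import average_precision_score

    y = _to_binary(labels)
    if y.min() == y.max():
        raise EvaluationError("average precision needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def phi_drop(auc_all: float, auc_sub: float) -> float:
    """Relative performance drop on a subset: (AUC_all - AUC_sub)/(AUC_all - 0.5).

    Used to quantify how much worse a predictor does on, e.g., variants in
    intrinsically disordered regions relative to its overall performance.
    Returned as a fraction; multiply by 100 to report a percentage.
    """
    if auc_all <= 0.5:
        raise EvaluationError(f"AUC_all must exceed 0.5, got {auc_all}")
    return (auc_all - auc_sub) / (auc_all - 0.5)


def auc_ci_halfwidth(auc: float, n_pos: int, n_neg: int, z: float = 1.96) -> float:
    """Hanley-McNeil normal-approximation half-width of an AUC confidence band."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return z * float(np.sqrt(max(var, 0.0)))
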