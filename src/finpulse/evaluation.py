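"""Binary-detector evaluation: confusion counts, threshold metrics, ROC/AUC.

Conventions pinned for the whole pipeline: precision is the proportion of
detections that are true pulses, recall the proportion of true pulses
detected, F1 their harmonic mean; FPR = fp/(fp+tn) and FNR = fn/(fn+tp)
are the exact rates later consumed by the trend-ribbon scaling.  Ratios
with a zero denominator are reported as missing (NaN) with a warning —
never silently as zero.  AUC is the trapezoid-rule area under the ROC
curve over all distinct score thresholds, and the "optimal" threshold is
the Youden's-J maximiser (TPR - FPR), ties broken toward 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "DetectorMetrics",
    "confusion",
    "metrics",
    "f1_from_precision_recall",
    "roc",
    "optimal_threshold",
]


@dataclass
class DetectorMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    fpr: float
    fnr: float
    auc: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return a.astype(int)


def confusion(labels, predictions) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) counts; the four partition the dataset."""
    labels = _check_binary(labels, "labels")
    predictions = _check_binary(predictions, "predictions")
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    cm = _sk_confusion(labels, predictions, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    return int(tp), int(fp), int(tn), int(fn)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as missing")
        return float("nan")
    return num / den


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(conf: tuple[int, int, int, int]) -> DetectorMetrics:
    """Threshold-dependent metrics from a (tp, fp, tn, fn) tuple."""
    tp, fp, tn, fn = conf
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion")
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    if np.isnan(precision) or np.isnan(recall):
        f1 = float("nan")
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = f1_from_precision_recall(precision, recall)
    return DetectorMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
        f1=f1,
        fpr=_safe_ratio(fp, fp + tn, "FPR"),
        fnr=_safe_ratio(fn, fn + tp, "FNR"),
    )


def roc(labels, probabilities) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoid AUC.

    Returns (fpr, tpr, thresholds, auc).  TPR/FPR are evaluated at every
    distinct score plus the all-negative endpoint; both classes must be
    present.  A score exactly at a threshold counts as positive,
    consistent with :func:`finpulse.detector.classify`.
    """
    labels = _check_binary(labels, "labels")
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, probabilities, drop_intermediate=False)
    return fpr, tpr, thresholds, float(_trapezoid_auc(fpr, tpr))


def optimal_threshold(labels, probabilities) -> float:
    """ROC-derived operating point: maximise Youden's J = TPR - FPR.

    Among thresholds tying on J, the candidate nearest 0.5 is returned
    (standard practice rounds the operating threshold toward 0.5 anyway).
    """
    fpr, tpr, thresholds, _ = roc(labels, probabilities)
    j = tpr - fpr
    # drop the synthetic inf threshold endpoint added by the curve
    finite = np.isfinite(thresholds)
    j, thresholds = j[finite], thresholds[finite]
    best = j.max()
    candidates = thresholds[np.isclose(j, best)]
    return float(candidates[np.argmin(np.abs(candidates - 0.5))])
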