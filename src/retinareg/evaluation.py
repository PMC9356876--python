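"""Evaluation metrics: confusion-matrix scores, ROC AUC, point-detection
matching, and the registration success-rate curve over error thresholds
0-25 px with its normalized AUC."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .registration import transform_points
from .types import ConfusionCounts, CorrespondenceSet, Homography, JunctionPoint

__all__ = [
    "confusion_metrics",
    "roc_auc",
    "match_detections",
    "registration_error",
    "SuccessRateCurve",
    "success_rate_curve",
]

UNDEFINED = float("nan")


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, precision and F1 from counts.

    A metric whose denominator is zero (or which needs an undefined TN) is
    reported as NaN rather than raised.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    out = {
        "sensitivity": tp / (tp + fn) if tp + fn > 0 else UNDEFINED,
        "precision": tp / (tp + fp) if tp + fp > 0 else UNDEFINED,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else UNDEFINED,
    }
    if tn is None:
        out["specificity"] = UNDEFINED
        out["accuracy"] = UNDEFINED
    else:
        out["specificity"] = tn / (tn + fp) if tn + fp > 0 else UNDEFINED
        total = tp + tn + fp + fn
        out["accuracy"] = (tp + tn) / total if total > 0 else UNDEFINED
    return out


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (equivalently the concordance statistic,
    with ties rank-averaged)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def match_detections(
    pred: list, truth: list, tolerance: float = 5.0
) -> ConfusionCounts:
    """Greedy one-to-one assignment of predictions to ground-truth points.

    Candidate pairs within ``tolerance`` px are taken closest-first; each
    matched pair is a TP, leftover predictions are FPs and leftover truths
    FNs. TN is undefined for point detection.
    """
    if not pred or not truth:
        return ConfusionCounts(tp=0, fp=len(pred), fn=len(truth), tn=None)
    p = np.array([(q.row, q.col) for q in pred], dtype=np.float64)
    t = np.array([(q.row, q.col) for q in truth], dtype=np.float64)
    d = np.hypot(p[:, None, 0] - t[None, :, 0], p[:, None, 1] - t[None, :, 1])
    pairs = [
        (d[i, j], i, j)
        for i in range(len(p))
        for j in range(len(t))
        if d[i, j] <= tolerance
    ]
    pairs.sort()
    used_p, used_t = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i not in used_p and j not in used_t:
            used_p.add(i)
            used_t.add(j)
            tp += 1
    return ConfusionCounts(tp=tp, fp=len(p) - tp, fn=len(t) - tp, tn=None)


def registration_error(
    h: Homography, gt: CorrespondenceSet, statistic: str = "mean"
) -> float:
    """Control-point error: distance between each transformed sensed point
    and its reference partner, aggregated by mean (default), median or
    max."""
    mapped = transform_points(h, gt.sensed_points)
    d = np.hypot(*(mapped - gt.ref_points).T)
    if statistic == "mean":
        return float(np.mean(d))
    if statistic == "median":
        return float(np.median(d))
    if statistic == "max":
        return float(np.max(d))
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class SuccessRateCurve:
    """Registration success rate as a function of the error threshold,
    with the area under the curve normalized by the 25-px span."""

    thresholds: np.ndarray
    success_rates: np.ndarray
    auc: float


def success_rate_curve(
    errors, max_threshold: float = 25.0, step: float = 0.1
) -> SuccessRateCurve:
    """Fraction of image pairs with error <= t for t in [0, max_threshold].

    Failed registrations should be passed as ``inf`` so they count against
    the success rate at every threshold. The AUC is the trapezoidal area
    divided by ``max_threshold`` and therefore lies in [0, 1].
    """
    errors = np.asarray(list(errors), dtype=np.float64)
    if errors.size == 0:
        raise ValueError("at least one registration error is required")
    thresholds = np.arange(0.0, max_threshold + step / 2, step)
    rates = np.array([(np.mean(errors <= t)) for t in thresholds])
    auc = float(np.trapezoid(rates, thresholds) / max_threshold)
    return SuccessRateCurve(thresholds, rates, auc)
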