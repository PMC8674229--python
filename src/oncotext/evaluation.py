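"""Discrimination, calibration and operating-point metrics.

AUROC is the primary metric; a group whose labels show no variation is
reported with a "not enough variation" marker rather than a number.
Operating points (best F1, best Youden's index) are chosen by exhaustive
scan over the midpoints of adjacent distinct scores plus the two infinities,
with ties broken toward higher sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

NOT_ENOUGH_VARIATION = "not enough variation"


class InsufficientVariationError(ValueError):
    """Labels contain a single class; the metric is undefined."""


def _check_two_classes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0 or labels.min() == labels.max():
        raise InsufficientVariationError(
            "not enough variation in outcome label to evaluate"
        )
    return labels


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative,
    counting ties as 1/2."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise interpolation."""
    labels = _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores)))


def calibration_curve(probabilities, labels, n_bins: int = 10) -> pd.DataFrame:
    """Observed event rate vs mean predicted probability per equal-width bin
    on [0, 1]; empty bins are omitted."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probabilities, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b,
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(mask.sum()),
                "mean_predicted": float(probabilities[mask].mean()),
                "observed_rate": float(labels[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    criterion: str  # best_f1 | best_youden
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    youden: float


def _confusion_at(scores, labels, threshold):
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def pick_operating_point(scores, labels, criterion: str = "best_f1") -> OperatingPoint:
    """Exhaustive scan over candidate thresholds (midpoints of adjacent
    distinct sorted scores, plus -inf and +inf); ties toward higher
    sensitivity, then the lower threshold."""
    if criterion not in ("best_f1", "best_youden"):
        raise ValueError(f"unknown criterion {criterion!r}")
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf])
    )
    best = None
    best_value, best_sens = -np.inf, -1.0
    tol = 1e-12  # mathematical ties must not be broken by rounding noise
    for thr in candidates:
        tp, fp, fn, tn = _confusion_at(scores, labels, thr)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        youden = sens + spec - 1.0
        value = f1 if criterion == "best_f1" else youden
        better = value > best_value + tol
        tie_more_sensitive = abs(value - best_value) <= tol and sens > best_sens + tol
        if best is None or better or tie_more_sensitive:
            best_value, best_sens = value, sens
            npv = tn / (tn + fn) if tn + fn else 0.0
            best = OperatingPoint(
                threshold=float(thr),
                criterion=criterion,
                sensitivity=sens,
                specificity=spec,
                ppv=prec,
                npv=npv,
                f1=f1,
                youden=youden,
            )
    return best


def evaluate_by_group(scores, labels, groups) -> pd.DataFrame:
    """Per-group AUROC table; single-class groups get the variation marker."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    rows = []
    for g in sorted(map(str, set(groups))):
        mask = groups.astype(str) == g
        try:
            value = auroc(scores[mask], labels[mask])
            marker = ""
        except InsufficientVariationError:
            value = np.nan
            marker = NOT_ENOUGH_VARIATION
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "n_positive": int(np.sum(labels[mask] == 1)),
                "auroc": value,
                "note": marker,
            }
        )
    return pd.DataFrame(rows)


def attribute_false_positives(
    doc_ids, patient_ids, probabilities, labels, threshold: float
) -> pd.DataFrame:
    """Per-patient false-positive counts and the evaluation-set AUROC
    recomputed with each patient's documents removed.

    Ranks patients by false-positive burden; a patient whose manual labels
    systematically disagree with well-founded predictions (e.g. a planted
    annotation error) surfaces at the top, and ``auroc_excluding`` shows how
    discrimination changes when that patient is dropped.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    overall = auroc(probabilities, labels)
    rows = []
    for pid in sorted(set(map(str, patient_ids))):
        mask = patient_ids.astype(str) == pid
        fp = int(np.sum((probabilities[mask] > threshold) & (labels[mask] == 0)))
        rest = ~mask
        try:
            excl = auroc(probabilities[rest], labels[rest])
        except InsufficientVariationError:
            excl = np.nan
        rows.append(
            {
                "patient_id": pid,
                "n_documents": int(mask.sum()),
                "false_positives": fp,
                "auroc_excluding": excl,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["false_positives", "patient_id"], ascending=[False, True]
    )
    df.attrs["overall_auroc"] = overall
    return df.reset_index(drop=True)
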