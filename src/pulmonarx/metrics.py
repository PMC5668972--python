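"""Threshold classification of PIP predictions and agreement statistics.

The clinical question is binary: will PIP exceed 40 cmH2O at the higher
PEEP?  Predictions and measurements are both dichotomised at the threshold
(strictly greater than), yielding confusion matrices, sensitivity and
specificity per prediction horizon.  Sweeping the discrimination threshold
over the predicted-PIP scores gives ROC curves with trapezoidal AUC and
two optimal-operating-point rules (closest to (0,1), Youden index), and
Bland-Altman summaries quantify measured-minus-predicted agreement.

Conventions fixed here rather than delegated to a generic library:
positives use strict ">" at the threshold, ROC thresholds sweep every
distinct score plus +-infinity, and threshold ties resolve toward the
higher threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InvalidInputError

DEFAULT_THRESHOLD = 40.0


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    """Operating points ordered by increasing threshold.

    ``thresholds`` includes -inf and +inf anchors, so the curve runs from
    (FPR, TPR) = (1, 1) down to (0, 0).  ``auc`` is NaN when only one
    outcome class is present.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def interior(self):
        """Operating points at finite thresholds (actual score values)."""
        mask = np.isfinite(self.thresholds)
        return self.thresholds[mask], self.fpr[mask], self.tpr[mask]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _check_finite(results):
    for r in results:
        if not (math.isfinite(r.predicted_pip) and math.isfinite(r.measured_pip)):
            raise InvalidInputError("non-finite PIP in prediction results")


def classify(results, threshold: float = DEFAULT_THRESHOLD) -> ConfusionMatrix:
    """Confusion matrix of above-threshold classification.

    Positive means PIP strictly greater than ``threshold``; a prediction
    exactly at the threshold counts as negative.
    """
    if not results:
        raise InvalidInputError("classify requires at least one result")
    _check_finite(results)
    tp = fp = tn = fn = 0
    for r in results:
        pred_pos = r.predicted_pip > threshold
        meas_pos = r.measured_pip > threshold
        if pred_pos and meas_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif meas_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); NaN when no positives were measured."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else math.nan


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP); NaN when no negatives were measured."""
    denom = cm.tn + cm.fp
    return cm.tn / denom if denom else math.nan


def round2(value: float) -> float:
    """Round to 2 decimals, half away from zero (report precision)."""
    if not math.isfinite(value):
        return value
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def roc_curve(
    results, outcome_threshold: float = DEFAULT_THRESHOLD
) -> RocCurve:
    """ROC over predicted-PIP scores, labels from measured PIP.

    The discrimination threshold sweeps every distinct score plus -inf and
    +inf; a case is called positive when its score strictly exceeds the
    threshold.  AUC is the trapezoidal area; with a single outcome class
    the rates on the missing side (and the AUC) are NaN.
    """
    if not results:
        raise InvalidInputError("roc_curve requires at least one result")
    _check_finite(results)
    scores = np.array([r.predicted_pip for r in results], dtype=float)
    labels = np.array(
        [r.measured_pip > outcome_threshold for r in results], dtype=bool
    )
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    thresholds = np.concatenate(
        [[-np.inf], np.unique(scores), [np.inf]]
    )
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        pred_pos = scores > th
        tpr[i] = (pred_pos & labels).sum() / n_pos if n_pos else math.nan
        fpr[i] = (pred_pos & ~labels).sum() / n_neg if n_neg else math.nan
    if n_pos and n_neg:
        order = np.lexsort((tpr, fpr))
        auc = float(np.trapezoid(tpr[order], fpr[order]))
    else:
        auc = math.nan
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def optimal_threshold(curve: RocCurve, method: str = "closest_01") -> float:
    """Optimal discrimination threshold from a ROC curve.

    ``closest_01`` minimises the Euclidean distance to the ideal corner
    (FPR, TPR) = (0, 1); ``youden`` maximises TPR - FPR.  Only finite
    (interior) thresholds compete, and ties break toward the higher
    threshold.
    """
    th, fpr, tpr = curve.interior()
    if th.size == 0:
        raise InvalidInputError("ROC curve has no interior operating point")
    if method == "closest_01":
        score = -np.sqrt(fpr**2 + (1.0 - tpr) ** 2)
    elif method == "youden":
        score = tpr - fpr
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    best = np.flatnonzero(score == score.max())
    return float(th[best[-1]])  # thresholds are sorted ascending


def bland_altman(results) -> dict:
    """Bland-Altman summary of measured - predicted PIP differences.

    Returns the mean difference (bias) and the 25th/50th/75th percentiles
    (linear interpolation between order statistics).
    """
    if not results:
        raise InvalidInputError("bland_altman requires at least one result")
    _check_finite(results)
    d = np.array([r.measured_pip - r.predicted_pip for r in results], dtype=float)
    q25, q50, q75 = np.percentile(d, [25, 50, 75])
    return {
        "bias": float(np.mean(d)),
        "p25": float(q25),
        "p50": float(q50),
        "p75": float(q75),
    }
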