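"""Classification metrics, ROC/PR curves, and specificity-calibrated
confidence thresholds.

The decision rule everywhere is: predicted positive iff score >= threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

TIER_TARGETS = {"moderate": 0.90, "high": 0.95, "very_high": 0.99}


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ConfidenceThresholds:
    moderate: float
    high: float
    very_high: float

    def __post_init__(self):
        if not self.moderate <= self.high <= self.very_high:
            raise ValueError("thresholds must be non-decreasing")

    def tier(self, score: float) -> str:
        if score >= self.very_high:
            return "very_high"
        if score >= self.high:
            return "high"
        if score >= self.moderate:
            return "moderate"
        return "none"

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {"moderate": self.moderate, "high": self.high,
                 "very_high": self.very_high},
                handle,
                indent=2,
            )
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "ConfidenceThresholds":
        with open(path) as handle:
            data = json.load(handle)
        return cls(data["moderate"], data["high"], data["very_high"])


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores and labels differ in length: {scores.shape} vs {labels.shape}"
        )
    predicted = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(predicted & (labels == 1))),
        TN=int(np.sum(~predicted & (labels == 0))),
        FP=int(np.sum(predicted & (labels == 0))),
        FN=int(np.sum(~predicted & (labels == 1))),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, F1, and MCC.

    A zero MCC denominator yields MCC = 0 with ``mcc_undefined`` set;
    other zero denominators yield NaN.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc_undefined = mcc_den == 0
    mcc = 0.0 if mcc_undefined else (tp * tn - fp * fn) / mcc_den
    return {
        "accuracy": (tp + tn) / counts.total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
        "mcc": float(mcc),
        "mcc_undefined": bool(mcc_undefined),
    }


def roc_pr(scores, labels) -> dict:
    """ROC and PR curves with their areas.

    AUPR uses the interpolation-free step rule (average precision).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute curves")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "precision": precision,
        "recall": recall,
        "pr_thresholds": pr_thr,
        "auroc": float(auc(fpr, tpr)),
        "aupr": float(average_precision_score(labels, scores)),
    }


def calibrate_confidence(
    validation_scores,
    validation_labels,
    targets: dict[str, float] | None = None,
) -> ConfidenceThresholds:
    """Specificity-calibrated score cutoffs from validation negatives.

    For each target specificity s the threshold is the smallest observed
    negative score t with ``mean(neg < t) >= s`` (an empirical quantile;
    no interpolation).  If no observed score qualifies, the cutoff is
    placed just above the maximum negative score.
    """
    targets = targets or TIER_TARGETS
    scores = np.asarray(validation_scores, dtype=float)
    labels = np.asarray(validation_labels, dtype=int)
    neg = np.sort(scores[labels == 0])
    if neg.size == 0:
        raise ValueError("no negatives in the validation set")
    if neg.size < 100:
        warnings.warn(
            f"only {neg.size} validation negatives; the 99%-specificity "
            "tier is unstable"
        )
    above_max = np.nextafter(neg[-1], np.inf)
    candidates = np.append(np.unique(neg), above_max)
    cutoffs = {}
    for name, s in targets.items():
        chosen = above_max
        for t in candidates:
            # specificity at threshold t under the score>=t decision rule
            if np.sum(neg < t) / neg.size >= s:
                chosen = float(t)
                break
        cutoffs[name] = chosen
    return ConfidenceThresholds(
        moderate=cutoffs["moderate"],
        high=cutoffs["high"],
        very_high=cutoffs["very_high"],
    )
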