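"""Evaluation primitives: F1, ROC AUC, confusion metrics, Spearman,
and concordance of predicted calls against published labels.

"Sensitive" is the positive class throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts sum to zero")

    @classmethod
    def from_calls(cls, predicted, actual) -> "ConfusionCounts":
        p = np.asarray(predicted, dtype=int)
        a = np.asarray(actual, dtype=int)
        return cls(
            tp=int(((p == 1) & (a == 1)).sum()),
            fp=int(((p == 1) & (a == 0)).sum()),
            tn=int(((p == 0) & (a == 0)).sum()),
            fn=int(((p == 0) & (a == 1)).sum()),
        )


def f1(counts: ConfusionCounts) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); 0 when the denominator vanishes."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 0.0 if denom == 0 else 2 * counts.tp / denom


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); undefined ratios come back NaN."""
    total = counts.tp + counts.fp + counts.tn + counts.fn
    accuracy = (counts.tp + counts.tn) / total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sensitivity = counts.tp / pos if pos else math.nan
    specificity = counts.tn / neg if neg else math.nan
    return accuracy, sensitivity, specificity


def roc_auc(probabilities, labels) -> float:
    """ROC AUC as the Mann-Whitney pairwise-concordance probability.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos == score_neg)
    over all positive/negative pairs; ties in the scores earn half
    credit. NaN for single-class input.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = stats.rankdata(p)  # average ranks handle ties -> 0.5 credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement of predicted binary calls with published labels."""

    n_overlap: int
    n_consistent: int
    accuracy: float
    sensitivity: float
    specificity: float


def concordance_report(
    pred_calls: pd.Series, published_calls: pd.Series
) -> ConcordanceReport:
    """Compare calls joined on drug id; NA published labels are excluded."""
    joined = pd.concat(
        {"pred": pred_calls, "published": published_calls}, axis=1, join="inner"
    ).dropna()
    if joined.empty:
        raise ValueError("empty overlap between predictions and published labels")
    counts = ConfusionCounts.from_calls(joined["pred"], joined["published"])
    accuracy, sensitivity, specificity = confusion_metrics(counts)
    return ConcordanceReport(
        n_overlap=len(joined),
        n_consistent=counts.tp + counts.tn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
    )
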