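"""Confusion-matrix metrics, ROC/AUC, and between-group index comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "GroupComparisonResult",
    "confusion_metrics",
    "roc_auc",
    "group_compare",
    "compare_feature_groups",
    "recording_duration",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is "high quality"."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.total == 0:
            raise ValueError("confusion matrix must count at least one unit")

    @property
    def total(self):
        return self.tp + self.fn + self.tn + self.fp


def confusion_metrics(cm: ConfusionMatrix):
    """Accuracy, sensitivity and specificity, each in percent.

    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

    Computed in exact rational arithmetic and returned at full float
    precision; round to two decimals for display.  A metric whose
    denominator is zero is returned as NaN.
    """
    accuracy = float(100 * Fraction(cm.tp + cm.tn, cm.total))
    sensitivity = float(100 * Fraction(cm.tp, cm.tp + cm.fn)) if cm.tp + cm.fn else float("nan")
    specificity = float(100 * Fraction(cm.tn, cm.tn + cm.fp)) if cm.tn + cm.fp else float("nan")
    return accuracy, sensitivity, specificity


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve for binary labels.

    Equals the Mann-Whitney rank statistic: the probability that a random
    positive unit scores above a random negative one, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    neg = ~pos
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-group comparison of one index with the study's significance flags."""

    index: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: float
    flag: str  # "*" for p < 0.05, "+" for 0.05 < p < 0.1, "" otherwise


def _flag(p):
    if p < 0.05:
        return "*"
    if 0.05 < p < 0.1:
        return "+"
    return ""


def group_compare(values_a, values_b, index="", paired=False) -> GroupComparisonResult:
    """Compare one index between two groups with a two-sided t test.

    The default is Welch's unequal-variance test; ``paired=True`` uses the
    paired test (the two contact pressures were applied to the same
    subjects).  Zero variance in both groups with equal means gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if (paired and np.allclose(a, b)) or (not paired and a.mean() == b.mean()) else 0.0
    elif paired:
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return GroupComparisonResult(
        index=index,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        p_value=p,
        flag=_flag(p),
    )


def compare_feature_groups(features, by="regime", paired=False) -> pd.DataFrame:
    """Group-compare all 40 indices of a beat feature table.

    ``by="regime"`` contrasts appropriate vs higher contact pressure;
    ``by="label"`` contrasts high- vs low-quality beats.  Group A is the
    reference (appropriate / high).  Returns one row per index with group
    means, SDs, the p value and the significance flag.
    """
    from .features import FEATURE_COLUMNS

    if by == "regime":
        mask_a = features["regime"] == "appropriate"
    elif by == "label":
        mask_a = features["label"] == "high"
    else:
        raise ValueError("by must be 'regime' or 'label'")
    rows = []
    for col in FEATURE_COLUMNS:
        res = group_compare(features.loc[mask_a, col], features.loc[~mask_a, col], index=col, paired=paired)
        rows.append(
            {
                "index": res.index,
                "mean_a": res.mean_a,
                "sd_a": res.sd_a,
                "mean_b": res.mean_b,
                "sd_b": res.sd_b,
                "p_value": res.p_value,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows).set_index("index")


def recording_duration(n_pulses, hr) -> float:
    """Seconds of recording needed to collect ``n_pulses`` beats at heart rate ``hr``.

    E.g. 30 pulses at 72 beats/min require 30/72 * 60 = 25 s.
    """
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    if n_pulses < 0:
        raise ValueError("pulse count must be non-negative")
    return n_pulses / hr * 60.0
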