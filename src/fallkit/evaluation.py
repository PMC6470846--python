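"""Slice-level scoring: confusion counts, metrics and statistical tests.

"fall" is the positive class throughout.  Metrics are returned as
full-precision proportions; formatting to percent is left to the caller
(the CLI prints 4 decimals).  A metric whose denominator is zero is
returned as NaN, an explicit "undefined" marker, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .io import LABEL_FALL

#: One-minute slices per week (7 * 24 * 60).
SLICES_PER_WEEK = 10080


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN over labelled slices (positive class = "fall")."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


#: Published confusion counts of the two field phases of the study this
#: package models (first-generation algorithm over 59 days, optimized
#: second-generation algorithm over 66 days); used by ``reproduce-table2``.
PHASE1_COUNTS = ConfusionCounts(tp=3, tn=675350, fp=29, fn=8)
PHASE2_COUNTS = ConfusionCounts(tp=16, tn=735840, fp=12, fn=4)
PHASE1_SLICES = 675390
PHASE2_SLICES = 735872


def confusion(labels, preds) -> ConfusionCounts:
    """Tally slice-level predictions against ground truth."""
    labels = np.asarray(labels, dtype=object)
    preds = np.asarray(preds, dtype=object)
    if len(labels) != len(preds):
        raise ValueError("labels and predictions length mismatch")
    truth = labels == LABEL_FALL
    pos = preds == LABEL_FALL
    return ConfusionCounts(
        tp=int(np.sum(truth & pos)),
        tn=int(np.sum(~truth & ~pos)),
        fp=int(np.sum(~truth & pos)),
        fn=int(np.sum(truth & ~pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, precision and F-measure.

    All values are proportions in [0, 1]; NaN marks an undefined metric
    (zero denominator).
    """
    sens = _ratio(cc.tp, cc.tp + cc.fn)
    spec = _ratio(cc.tn, cc.tn + cc.fp)
    acc = _ratio(cc.tp + cc.tn, cc.total)
    prec = _ratio(cc.tp, cc.tp + cc.fp)
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        f = float("nan")
    else:
        f = 2 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "precision": prec, "f_measure": f}


def false_alarm_rate(cc: ConfusionCounts, n_slices: int,
                     n_subjects: Optional[int] = None) -> float:
    """False alarms per week of recording: fp / (n_slices / 10080).

    With ``n_subjects`` given, the rate is further divided by the number of
    subjects (per-subject-week normalization); the plain per-week rate is
    the default because the recorded duration already aggregates subjects.
    """
    if n_slices <= 0:
        raise ValueError("n_slices must be positive")
    rate = cc.fp / (n_slices / SLICES_PER_WEEK)
    if n_subjects is not None:
        rate /= n_subjects
    return rate


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table, df = 1.

    No continuity correction.  Both margins must be positive.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t distribution, n-2 df).

    Returns (nan, nan) when either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def evaluation_report(labels, preds, n_slices: Optional[int] = None) -> dict:
    """Bundle counts, metrics and the false-alarm rate into one dict."""
    cc = confusion(labels, preds)
    n = n_slices if n_slices is not None else cc.total
    return {
        "counts": {"tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn},
        "metrics": metrics(cc),
        "false_alarms_per_week": false_alarm_rate(cc, n),
        "n_slices": n,
    }
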