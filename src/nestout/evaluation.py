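"""Confusion matrices, classifier quality measures and outlier accounting.

The four binary measures are accuracy ACC = (TP+TN)/(TP+TN+FP+FN),
precision PP = TP/(TP+FP), sensitivity SE = TP/(TP+FN) and specificity
SP = TN/(TN+FP); a measure whose denominator is zero is reported as 0.
Multiclass tables are reduced one-vs-rest to per-class binary counts.
Outlier accounting separates correctly detected outliers (true and
predicted) from overdetected ones (predicted but belonging to a known
activity), the negative statistic that counterbalances raw detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "binary_metrics",
    "multiclass_confusion",
    "OutlierReport",
    "outlier_report",
    "round_half_away",
]


def round_half_away(x: float, digits: int = 2) -> float:
    """Round half away from zero (the convention used in printed tables)."""
    scale = 10**digits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, true01, pred01) -> "ConfusionMatrix":
        t = np.asarray(true01, dtype=bool)
        p = np.asarray(pred01, dtype=bool)
        if t.shape != p.shape:
            raise ValueError("label vectors must have equal length")
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
            fn=int(np.sum(t & ~p)),
        )


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def binary_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """ACC, PP, SE, SP from binary counts; 0-denominator measures are 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "ACC": _ratio(cm.tp + cm.tn, cm.total),
        "PP": _ratio(cm.tp, cm.tp + cm.fp),
        "SE": _ratio(cm.tp, cm.tp + cm.fn),
        "SP": _ratio(cm.tn, cm.tn + cm.fp),
    }


def multiclass_confusion(
    true_labels, predicted_labels
) -> tuple[pd.DataFrame, dict[str, ConfusionMatrix]]:
    """k x k confusion table plus one-vs-rest binary reductions per class.

    Cell (i, j) counts records with true class i predicted as class j.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    classes = sorted(set(true_labels) | set(predicted_labels), key=str)
    table = _sk_confusion(true_labels, predicted_labels, labels=classes)
    frame = pd.DataFrame(table, index=classes, columns=classes)

    total = int(table.sum())
    reductions: dict[str, ConfusionMatrix] = {}
    for i, cls in enumerate(classes):
        tp = int(table[i, i])
        fp = int(table[:, i].sum()) - tp
        fn = int(table[i, :].sum()) - tp
        reductions[cls] = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=total - tp - fp - fn)
    return frame, reductions


@dataclass(frozen=True)
class OutlierReport:
    """Detected vs overdetected outlier accounting.

    ``n_detected`` counts predicted outliers that truly come from an
    unknown activity; ``n_overdetected`` counts predicted outliers whose
    true label is a known activity.  ``detection_pct`` is
    100 * n_detected / n_true_outliers (0, with ``undefined_pct`` set, when
    there are no true outliers).
    """

    n_true_outliers: int
    n_detected: int
    n_overdetected: int
    detection_pct: float
    undefined_pct: bool = False

    @property
    def n_predicted(self) -> int:
        return self.n_detected + self.n_overdetected


def outlier_report(result, true_labels: pd.Series) -> OutlierReport:
    """Score a nested-classification result against true test labels.

    A test record is a true outlier iff its label is outside the activity
    set the cascade was run with.
    """
    true_labels = pd.Series(true_labels)
    missing = result.assignment.index.difference(true_labels.index)
    if len(missing):
        raise ValueError("true labels must cover every test record")
    known = set(result.activities)
    truth = true_labels.loc[result.assignment.index]
    true_out = set(truth.index[~truth.isin(known)])
    predicted = set(result.outlier_indices)

    n_detected = len(predicted & true_out)
    n_over = len(predicted - true_out)
    if true_out:
        return OutlierReport(
            n_true_outliers=len(true_out),
            n_detected=n_detected,
            n_overdetected=n_over,
            detection_pct=100.0 * n_detected / len(true_out),
        )
    return OutlierReport(
        n_true_outliers=0,
        n_detected=0,
        n_overdetected=n_over,
        detection_pct=0.0,
        undefined_pct=True,
    )


def render_level_table(levels) -> str:
    """Per-level quality table (percent, 2 decimals, half-away rounding)."""
    rows = []
    for lv in levels:
        row = {"level": lv.level, "activity": lv.activity}
        if lv.metrics is not None:
            row.update(
                {k: round_half_away(100.0 * v) for k, v in lv.metrics.items()}
            )
        row["assigned"] = lv.n_assigned
        rows.append(row)
    return pd.DataFrame(rows).to_string(index=False)
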