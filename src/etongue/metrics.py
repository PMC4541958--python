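"""Classification indicators from confusion matrices.

Three indicators summarize a 4-class confusion matrix (rows = expected,
columns = predicted):

* accuracy — 100 x trace / total;
* per-class sensitivity — percentage of a class's samples identified,
  100 x cm[i,i] / row_i;
* per-class specificity — percentage of other-class samples correctly
  rejected, 100 x TN_i / (TN_i + FP_i) with FP_i = column_i - cm[i,i] and
  TN_i = total - row_i - FP_i.

Macro values are unweighted means over the four classes.  All percentages
are reported to one decimal, rounded half away from zero — this convention
reproduces values such as 98.3 (from 98.33...), 81.7 (81.66...) and 69.2
(69.16...) exactly.  When all row sums are equal (a balanced design),
accuracy and macro sensitivity coincide identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import ConfusionMatrix


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class MetricsReport:
    """Indicators of one confusion matrix, percentages to one decimal."""

    accuracy: float
    per_class_sensitivity: tuple[float, ...]
    per_class_specificity: tuple[float, ...]
    macro_sensitivity: float
    macro_specificity: float
    n_correct: int
    classes: tuple[str, ...]


def correct_count(cm: ConfusionMatrix) -> int:
    """Number of correctly classified samples (matrix trace)."""
    return cm.trace


def score(cm: ConfusionMatrix) -> MetricsReport:
    """Compute accuracy, per-class and macro sensitivity/specificity."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    diag = np.diag(counts)
    if np.any(rows == 0):
        bad = cm.classes[int(np.argmax(rows == 0))]
        raise ValueError(f"sensitivity undefined: class {bad} has no samples")
    fp = cols - diag
    tn = total - rows - fp
    if np.any(tn + fp == 0):
        bad = cm.classes[int(np.argmax(tn + fp == 0))]
        raise ValueError(f"specificity undefined for class {bad}")
    sens = 100.0 * diag / rows
    spec = 100.0 * tn / (tn + fp)
    return MetricsReport(
        accuracy=_round1(100.0 * diag.sum() / total),
        per_class_sensitivity=tuple(_round1(s) for s in sens),
        per_class_specificity=tuple(_round1(s) for s in spec),
        macro_sensitivity=_round1(float(sens.mean())),
        macro_specificity=_round1(float(spec.mean())),
        n_correct=int(diag.sum()),
        classes=cm.classes,
    )
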