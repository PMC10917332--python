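"""Binary classification-performance metrics with a fixed confusion-matrix
orientation.

The confusion matrix here always has rows = true class, columns = predicted
class; class 2 (habitual diver) is the positive class.  Some discriminant
codebases emit the transpose of this layout, so a ``transposed_legacy`` view
is provided for comparison with such output.

Besides accuracy A, balanced accuracy B and the Matthews correlation
coefficient MCC, the set includes the heuristic

    P_rand = 2·(1 - A),

the fraction of purely random classifications that would produce the same
accuracy as the observed classifier (a coin-flip is right half the time, so
A = 0.5·P_rand + 1·(1 - P_rand)).  It is clipped to [0, 1]: below-chance
classifiers (A < 0.5) are outside the heuristic's domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricSet", "confusion", "metrics", "threshold_sweep"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    tp: int  # true 2 predicted 2
    fn: int  # true 2 predicted 1
    fp: int  # true 1 predicted 2
    tn: int  # true 1 predicted 1

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix entries must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        """[[tn, fp], [fn, tp]]: row i = true class i+1, column j = predicted j+1."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def transposed_legacy(self) -> np.ndarray:
        """Rows = predicted, columns = true (the orientation some
        discriminant codebases print)."""
        return self.as_array().T


@dataclass(frozen=True)
class MetricSet:
    A: float       # accuracy
    B: float       # balanced accuracy (mean per-class recall)
    MCC: float     # Matthews correlation coefficient
    P_rand: float  # 2(1 - A), clipped to [0, 1]
    tpr: float
    fpr: float


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally a confusion matrix from 1/2 label sequences."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    for arr, name in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr)) - {1, 2}
        if bad:
            raise ValueError(f"{name} labels outside {{1, 2}}: {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(np.sum((t == 2) & (p == 2))),
        fn=int(np.sum((t == 2) & (p == 1))),
        fp=int(np.sum((t == 1) & (p == 2))),
        tn=int(np.sum((t == 1) & (p == 1))),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """All performance metrics for one confusion matrix."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    a = (cm.tp + cm.tn) / n
    n2 = cm.tp + cm.fn  # true class-2 count
    n1 = cm.tn + cm.fp
    tpr = cm.tp / n2 if n2 else math.nan
    tnr = cm.tn / n1 if n1 else math.nan
    fpr = cm.fp / n1 if n1 else math.nan
    b = np.nanmean([tpr, tnr])
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = 0.0 if denom == 0 else (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return MetricSet(
        A=a,
        B=float(b),
        MCC=float(mcc),
        P_rand=float(np.clip(2.0 * (1.0 - a), 0.0, 1.0)),
        tpr=float(tpr) if not math.isnan(tpr) else math.nan,
        fpr=float(fpr) if not math.isnan(fpr) else math.nan,
    )


def threshold_sweep(posteriors, true_labels, grid) -> list[MetricSet]:
    """One metric set per classification threshold (ROC-style sweep).

    A record is predicted class 2 when its class-2 posterior is >= the
    threshold, so tpr is non-increasing as the threshold rises.
    """
    p2 = np.asarray(posteriors, float)
    t = np.asarray(true_labels)
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    out = []
    for thr in grid:
        pred = np.where(p2 >= thr, 2, 1)
        out.append(metrics(confusion(t, pred)))
    return out
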