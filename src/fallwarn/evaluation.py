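"""Alarm-quality evaluation: confusion matrices, rates and ROC curves.

Clips whose expert ground-truth risk exceeds the alarm threshold (0.5 by
default) are the positive class.  Counts use exact integer arithmetic;
rates are reported as percentages.  The ROC curve sweeps the alarm
threshold over the overall-risk scores with the strict-inequality alarm
rule, yielding the usual monotone staircase from (0, 0) to (1, 1).
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Alarm counts on one disjoint clip set."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError("counts must be non-negative")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.FP + self.TN


def confusion(labels: Sequence[float], alarms: Sequence[bool],
              T: float = 0.5) -> ConfusionMatrix:
    """Count alarm outcomes against expert risk labels (positive: p_GT > T)."""
    labels = np.asarray(labels, dtype=float)
    alarms = np.asarray(alarms, dtype=bool)
    if labels.shape != alarms.shape:
        raise ValueError("labels and alarms must have equal length")
    positive = labels > T
    return ConfusionMatrix(
        TP=int(np.count_nonzero(positive & alarms)),
        FP=int(np.count_nonzero(~positive & alarms)),
        FN=int(np.count_nonzero(positive & ~alarms)),
        TN=int(np.count_nonzero(~positive & ~alarms)),
    )


@dataclass(frozen=True)
class Metrics:
    """Accuracy / TPR / FPR in percent (exact rationals, floated)."""

    accuracy: float
    tpr: Optional[float]
    fpr: Optional[float]


def metrics(cm: ConfusionMatrix) -> Metrics:
    """(TP + TN)/(P + N), TP/P and FP/N as percentages.

    TPR / FPR are None when the corresponding class is empty.
    """
    total = cm.P + cm.N
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = Fraction(cm.TP + cm.TN, total) * 100
    tpr = Fraction(cm.TP, cm.P) * 100 if cm.P > 0 else None
    fpr = Fraction(cm.FP, cm.N) * 100 if cm.N > 0 else None
    return Metrics(float(acc),
                   float(tpr) if tpr is not None else None,
                   float(fpr) if fpr is not None else None)


def roc(labels: Sequence[float], overall_risks: Sequence[float],
        thresholds: Optional[Sequence[float]] = None, T_gt: float = 0.5
        ) -> tuple[np.ndarray, np.ndarray]:
    """ROC staircase (FPR, TPR) by sweeping the alarm threshold.

    ``thresholds`` defaults to the sorted unique scores; the endpoints
    (0, 0) and (1, 1) are always included.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(overall_risks, dtype=float)
    positive = labels > T_gt
    P = int(np.count_nonzero(positive))
    N = int(np.count_nonzero(~positive))
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes")
    if thresholds is None:
        thresholds = np.unique(scores)
    else:
        thresholds = np.sort(np.asarray(thresholds, dtype=float))
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for th in thresholds:
        fired = scores > th
        pts.add((np.count_nonzero(fired & ~positive) / N,
                 np.count_nonzero(fired & positive) / P))
    arr = np.array(sorted(pts))
    return arr[:, 0], arr[:, 1]


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under an ROC staircase by the trapezoid rule."""
    return float(np.trapezoid(tpr, fpr))


def auc_rank(labels: Sequence[float], overall_risks: Sequence[float],
             T_gt: float = 0.5) -> float:
    """AUC as the Mann-Whitney probability that a positive outscores a
    negative (ties count one half); the rank-statistic cross-check for
    :func:`auc_trapezoid`."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(overall_risks, dtype=float)
    pos = scores[labels > T_gt]
    neg = scores[labels <= T_gt]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes")
    greater = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def plot_roc(fpr: np.ndarray, tpr: np.ndarray, ax=None, label: Optional[str] = None):
    """Plot an ROC staircase (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(fpr, tpr, drawstyle="steps-post", label=label)
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    return ax
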