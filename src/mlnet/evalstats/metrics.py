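"""Classification and segmentation metrics.

The rank-based AUC here is the single formula source for every AUC the
package reports: (sum of positive ranks - M(M+1)/2) / (M*N) with midranks
for ties, which equals the probability that a random positive outranks a
random negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "OperatingPoint",
    "dice",
    "auc_rank",
    "confusion_metrics",
    "youden_threshold",
    "roc_curve",
]


def _scores_labels(scores, labels=None):
    """Accept a ScoreSet-like object (``.scores`` / ``.labels``) or two arrays."""
    if labels is None:
        scores, labels = scores.scores, scores.labels
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1D arrays")
    if s.size == 0:
        raise ValueError("empty score set")
    if not np.isin(np.unique(y), (0, 1)).all():
        raise ValueError("labels must be binary")
    return s, y.astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    counts: ConfusionCounts


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    youden_j: float

    def __post_init__(self):
        if not -1.0 <= self.youden_j <= 1.0 + 1e-12:
            raise ValueError("Youden J outside [-1, 1]")


def dice(pred, gt) -> float:
    """Overlap 2TP / (2TP + FP + FN) between two binary masks.

    Both masks empty -> 1.0 (perfect-agreement convention); an empty
    prediction against a nonempty reference scores 0.0.
    """
    p = np.asarray(getattr(pred, "data", pred))
    g = np.asarray(getattr(gt, "data", gt))
    if p.shape != g.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {g.shape}")
    sp_p = getattr(pred, "spacing", None)
    sp_g = getattr(gt, "spacing", None)
    if sp_p is not None and sp_g is not None and tuple(sp_p) != tuple(sp_g):
        raise ValueError("mask spacings differ")
    p = p.astype(bool)
    g = g.astype(bool)
    tp = int((p & g).sum())
    denom = 2 * tp + int((p & ~g).sum()) + int((~p & g).sum())
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def auc_rank(scores, labels=None) -> float:
    """Rank-sum AUC with midranks for ties."""
    s, y = _scores_labels(scores, labels)
    m = int(y.sum())
    n = int((1 - y).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # ascending serial numbers, midranks on ties
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def confusion_counts(scores, labels=None, threshold: float = 0.5) -> ConfusionCounts:
    s, y = _scores_labels(scores, labels)
    pred = s >= threshold  # classification rule fixed package-wide
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
        tn=int((~pred & (y == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str, warn: bool = True) -> float:
    if den == 0:
        if warn:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(scores, labels=None, threshold: float = 0.5,
                      warn: bool = True) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV and F1 at a threshold.

    A case is called positive iff score >= threshold. Ratios with zero
    denominators are reported as NaN with a warning, never silently as 0.
    """
    c = confusion_counts(scores, labels, threshold)
    return ConfusionMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity", warn),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity", warn),
        ppv=_ratio(c.tp, c.tp + c.fp, "PPV", warn),
        npv=_ratio(c.tn, c.tn + c.fn, "NPV", warn),
        f1=_f1(c, warn),
        counts=c,
    )


def _f1(c: ConfusionCounts, warn: bool) -> float:
    den = c.tp + 0.5 * (c.fp + c.fn)
    if den == 0:
        if warn:
            warnings.warn("F1 undefined (zero denominator); reporting NaN",
                          RuntimeWarning, stacklevel=3)
        return float("nan")
    return c.tp / den


def youden_threshold(scores, labels=None) -> OperatingPoint:
    """Operating point maximising sensitivity + specificity - 1.

    Candidate thresholds are the unique observed scores; ties in J break
    toward the smallest threshold. The returned threshold is meant to be
    transferred verbatim to external data.
    """
    s, y = _scores_labels(scores, labels)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("Youden threshold undefined: both classes must be present")
    best_thr, best_j = None, -np.inf
    for thr in np.unique(s):  # ascending, so first max wins the tie-break
        m = confusion_metrics(s, y, threshold=float(thr), warn=False)
        j = m.sensitivity + m.specificity - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    return OperatingPoint(threshold=best_thr, youden_j=float(best_j))


def roc_curve(scores, labels=None):
    """Monotone ROC staircase from (0,0) to (1,1).

    Ties are grouped, so the trapezoidal area equals ``auc_rank`` exactly.
    Returns (fpr, tpr) arrays.
    """
    s, y = _scores_labels(scores, labels)
    m = int(y.sum())
    n = y.size - m
    if m == 0 or n == 0:
        raise ValueError("ROC undefined: both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last index of each tied score group
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], y.size - 1]
    tpr = np.r_[0.0, tps[last] / m]
    fpr = np.r_[0.0, fps[last] / n]
    return fpr, tpr
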