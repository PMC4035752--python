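"""TP/FP rates, ROC curves and AUC under the union-ascertainment convention.

Because validation covers exactly the sites detected by at least one
caller, the union of all calls contains every true positive and every
false positive. All rates here use those union totals as denominators —
never per-caller candidate sets — so single callers appear as points and
score-ranked combined callers as curves on one common axis pair.
Rates are percentages (0-100); AUC is on the [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from callstack.data_model import DataError
from callstack.cumulative import SubsetOrdering, cumulative_rates
from callstack.venn import SubsetStats


@dataclass(frozen=True)
class RocCurve:
    """An ROC step curve in percent coordinates, from (0,0) to (100,100)."""

    points: tuple[tuple[float, float], ...]
    auc: float

    def __post_init__(self) -> None:
        fp = [p[0] for p in self.points]
        tp = [p[1] for p in self.points]
        if self.points[0] != (0.0, 0.0) or self.points[-1] != (100.0, 100.0):
            raise DataError("ROC curve must start at (0,0) and end at (100,100)")
        if any(b < a for a, b in zip(fp, fp[1:])) or any(b < a for a, b in zip(tp, tp[1:])):
            raise DataError("ROC coordinates must be non-decreasing")

    def tp_rate_at_fp(self, fp_rate: float) -> float:
        """TP rate of the step curve at a given FP rate (best achievable at that budget)."""
        best = 0.0
        for fp, tp in self.points:
            if fp <= fp_rate + 1e-12:
                best = max(best, tp)
        return best

    def dominates_point(self, fp_rate: float, tp_rate: float, strict: bool = True) -> bool:
        """Does the curve pass above a single (FP, TP) operating point?"""
        reach = self.tp_rate_at_fp(fp_rate)
        return reach > tp_rate if strict else reach >= tp_rate


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if set(np.unique(labels).tolist()) != {0, 1}:
        raise DataError("labels must contain both classes 0 and 1")
    return labels


def rates_of_call_set(predicted: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(FP rate %, TP rate %) of a set-valued caller against the union truth."""
    labels = _check_labels(labels)
    predicted = np.asarray(predicted).astype(bool)
    if predicted.shape != labels.shape:
        raise DataError("predicted and labels must have the same length")
    tp_rate = 100.0 * (predicted & (labels == 1)).sum() / (labels == 1).sum()
    fp_rate = 100.0 * (predicted & (labels == 0)).sum() / (labels == 0).sum()
    return float(fp_rate), float(tp_rate)


def roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve of a score-ranked caller; equal scores enter together.

    Thresholds sweep the distinct score values from stringent to liberal.
    AUC is the trapezoidal area of the [0,1]-scaled curve, which equals
    the Mann-Whitney pair statistic with ties counted 1/2. Sites may carry
    ``-inf`` scores (never called at any threshold short of "call all"):
    they form the final jump to (100, 100).
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have the same length")
    if np.isnan(scores).any():
        raise DataError("scores must not contain NaN")
    if np.isinf(scores).any():  # map +/-inf to finite sentinels; ranks are all that matter
        finite = scores[np.isfinite(scores)]
        lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 0.0)
        scores = np.clip(scores, lo - 1.0, hi + 1.0)
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    pts = [(100.0 * f, 100.0 * t) for f, t in zip(fpr, tpr)]
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (100.0, 100.0):
        pts.append((100.0, 100.0))
    return RocCurve(points=tuple(pts), auc=auc)


def roc_from_subset_order(ordering: SubsetOrdering, test_stats: list[SubsetStats]) -> RocCurve:
    """ROC curve of the cumulative combined caller on a test partition."""
    pts = [(0.0, 0.0)] + cumulative_rates(ordering, test_stats)
    fp = np.array([p[0] for p in pts]) / 100.0
    tp = np.array([p[1] for p in pts]) / 100.0
    return RocCurve(points=tuple(pts), auc=float(np.trapezoid(tp, fp)))


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force O(n^2) Mann-Whitney AUC (ties count 1/2); an independent oracle."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("labels must contain both classes 0 and 1")
    wins = 0.0
    for s in pos:
        wins += (s > neg).sum() + 0.5 * (s == neg).sum()
    return float(wins / (len(pos) * len(neg)))
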