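"""Detector scoring: ROC/AUC, Youden-J threshold, per-shape accuracy.

Scores are oriented so larger means "more cycling" (use -log10 p or
the persistence score).  Thresholds sit at midpoints between distinct
score values (plus sentinels beyond both extremes), so tied scores
move together and the trapezoidal AUC coincides with the Mann-Whitney
U statistic with half-credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from timecycle.synth import SHAPES

__all__ = ["RocCurve", "roc_auc", "youden_threshold",
           "percent_correct_by_shape", "neglog10_p"]


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending; call positive when score >= thr
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def neglog10_p(pvals: Sequence[float]) -> np.ndarray:
    return -np.log10(np.asarray(pvals, dtype=float))


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC over all distinct thresholds plus trapezoidal AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # descending thresholds: start above max (nothing called) and end
    # below min (everything called)
    thresholds = np.concatenate((
        [distinct[-1] + 1.0], mids[::-1], [distinct[0] - 1.0],
    ))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        calls = s >= thr
        tpr[i] = (calls & y).sum() / n_pos
        fpr[i] = (calls & ~y).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def youden_threshold(rc: RocCurve) -> float:
    """Threshold maximizing J = tpr - fpr; ties favor higher specificity."""
    j = rc.tpr - rc.fpr
    # lexicographic: max J, then min fpr, then larger threshold
    best = max(range(len(j)),
               key=lambda i: (j[i], -rc.fpr[i], rc.thresholds[i]))
    return float(rc.thresholds[best])


def percent_correct_by_shape(
    calls: Sequence[bool],
    shapes: Sequence[str],
    truth: Sequence[bool],
) -> Mapping[str, float]:
    """Per-shape fraction of genes whose call matches the truth label."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    shapes = np.asarray(shapes, dtype=object)
    if not (len(calls) == len(shapes) == len(truth)):
        raise ValueError("calls, shapes and truth must be aligned")
    unknown = sorted(set(shapes) - set(SHAPES))
    if unknown:
        raise ValueError(f"unknown shape labels: {unknown}")
    out: dict[str, float] = {}
    for shape in SHAPES:
        sel = shapes == shape
        if sel.any():
            out[shape] = float((calls[sel] == truth[sel]).mean())
    return out
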