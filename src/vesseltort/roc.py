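"""ROC curves: empirical staircases, upper-left convex hulls, vertical averaging.

Two kinds of ROC curve appear in the pipeline. Threshold sweeps over a
single score (the baseline metric) yield the usual empirical staircase.
The evolutionary weight search instead yields a cloud of operating points,
one per candidate solution, and the ROC curve is the upper-left convex hull
of that cloud anchored at (0, 0) and (1, 1) — every point on the hull is
achievable by randomizing between two candidate configurations. Curves from
different cross-validation splits are combined by vertical averaging: TPR is
linearly interpolated on a fixed FPR grid and averaged pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ContractViolationError, UndefinedStatisticError


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPR, TPR) points with nondecreasing coordinates in [0, 1]."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1 or fpr.size < 2:
            raise ContractViolationError("a ROC curve needs matching 1-d fpr/tpr, >= 2 points")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < -1e-12):
            raise ContractViolationError("ROC coordinates must be nondecreasing")
        if fpr.min() < 0 or fpr.max() > 1 or tpr.min() < 0 or tpr.max() > 1:
            raise ContractViolationError("ROC coordinates must lie in [0, 1]")
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    @property
    def auc(self) -> float:
        """Area under the curve by the trapezoid rule."""
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_staircase(scores, labels) -> ROCCurve:
    """Empirical ROC over all thresholds of a single score.

    Predictions use score >= threshold; the trapezoid AUC of the returned
    curve equals the Mann-Whitney concordant-pair statistic (ties counted
    half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise UndefinedStatisticError("ROC undefined: only one class present in labels")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr)


def _upper_envelope(fpr: np.ndarray, tpr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per unique FPR keep the maximum TPR; returns strictly increasing FPR."""
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    # fpr ascending, tpr ascending within fpr ties: the last position of each
    # unique fpr carries its max tpr; running max keeps the envelope monotone.
    env_tpr = np.maximum.accumulate(tpr)
    uniq = np.unique(fpr)
    positions = np.searchsorted(fpr, uniq, side="right") - 1
    return uniq, env_tpr[positions]


def roc_from_points(points) -> ROCCurve:
    """Upper-left convex-hull ROC through a cloud of (FPR, TPR) operating points.

    The cloud is anchored at (0, 0) and (1, 1); the returned curve is the
    concave upper frontier (nonincreasing slope) with strictly increasing
    FPR.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        raise ContractViolationError("need at least one operating point")
    if pts.min() < -1e-12 or pts.max() > 1 + 1e-12:
        raise ContractViolationError("operating points must lie in the unit square")
    pts = np.clip(pts, 0.0, 1.0)
    pts = np.vstack([pts, [[0.0, 0.0], [1.0, 1.0]]])
    fpr, tpr = _upper_envelope(pts[:, 0], pts[:, 1])
    # Andrew's monotone chain, upper hull in (fpr, tpr)
    hull: list[tuple[float, float]] = []
    for x, y in zip(fpr, tpr):
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1) >= 0:
                hull.pop()
            else:
                break
        hull.append((x, y))
    arr = np.asarray(hull)
    return ROCCurve(fpr=arr[:, 0], tpr=arr[:, 1])


def interpolate_rocs(curves, n_grid: int = 101) -> ROCCurve:
    """Vertical average of ROC curves on a fixed FPR grid.

    Each curve's TPR is linearly interpolated at the grid FPRs (duplicated
    FPR values collapse to their maximum TPR first) and the interpolants are
    averaged pointwise; the result is again a ROC curve.
    """
    curves = list(curves)
    if not curves:
        raise ContractViolationError("need at least one curve to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    acc = np.zeros_like(grid)
    for curve in curves:
        fpr, tpr = _upper_envelope(curve.fpr, curve.tpr)
        acc += np.interp(grid, fpr, tpr)
    mean_tpr = np.clip(acc / len(curves), 0.0, 1.0)
    return ROCCurve(fpr=grid, tpr=np.maximum.accumulate(mean_tpr))
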