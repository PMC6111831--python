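"""Boundary-detection evaluation: distance-tolerant precision/recall,
F-measure, P-R curves and average precision.

Predicted and ground-truth boundary pixels are matched one-to-one,
nearest pair first, within a Euclidean tolerance (default 0.0075× the
image diagonal, the de-facto boundary-benchmark convention). Greedy
nearest-first matching approximates the classical min-cost assignment
and coincides with it on fixtures without dense parallel structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import BoundaryGT
from .postprocess import non_maxima_suppress


def _as_consensus_mask(gt) -> np.ndarray:
    """Binarise a BoundaryGT consensus (or raw mask) at 0.5 (annotator majority)."""
    if isinstance(gt, BoundaryGT):
        return (gt.consensus >= 0.5).astype(np.float64)
    arr = np.asarray(gt, dtype=np.float64)
    return (arr >= 0.5).astype(np.float64)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean F = 2PR/(P+R), 0 when P + R = 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def match_boundaries(pred: np.ndarray, gt, tol: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching of predicted vs ground-truth pixels.

    Each predicted pixel may claim at most one unmatched ground-truth
    pixel within Euclidean distance ``tol``, closest pairs first.

    Returns (TP, FP, FN).
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    pred = np.asarray(pred, dtype=np.float64)
    gt_mask = _as_consensus_mask(gt)
    if pred.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt_mask.shape}")
    pred_pts = np.argwhere(pred > 0)
    gt_pts = np.argwhere(gt_mask > 0)
    n_pred, n_gt = len(pred_pts), len(gt_pts)
    if n_pred == 0 or n_gt == 0:
        return 0, n_pred, n_gt
    tree_pred = cKDTree(pred_pts)
    tree_gt = cKDTree(gt_pts)
    pairs = tree_pred.sparse_distance_matrix(tree_gt, tol, output_type="coo_matrix")
    order = np.argsort(pairs.data, kind="stable")
    pred_used = np.zeros(n_pred, dtype=bool)
    gt_used = np.zeros(n_gt, dtype=bool)
    tp = 0
    for idx in order:
        pi, gi = pairs.row[idx], pairs.col[idx]
        if pred_used[pi] or gt_used[gi]:
            continue
        pred_used[pi] = True
        gt_used[gi] = True
        tp += 1
    return tp, n_pred - tp, n_gt - tp


@dataclass(frozen=True)
class PRCurve:
    """P-R sweep over thresholds with its summary scores."""

    thresholds: np.ndarray  # decreasing
    precision: np.ndarray
    recall: np.ndarray
    f: np.ndarray
    ap: float
    best_f: float
    best_threshold: float


def pr_curve(
    response: np.ndarray,
    gt,
    n_thresholds: int = 20,
    tol: float | None = None,
    thin: bool = True,
) -> PRCurve:
    """Sweep evenly spaced thresholds over a [0, 1] response map.

    The response is thinned once (gradient-based non-maxima suppression)
    unless ``thin=False``, then binarised at each level and matched
    against the consensus ground truth. Levels are spaced relative to the
    response's own maximum so maps with different dynamic ranges are
    swept comparably. AP is the trapezoidal area under P(R); best_F is
    the maximum F over levels.
    """
    response = np.asarray(response, dtype=np.float64)
    if response.min() < 0 or response.max() > 1:
        raise ValueError("response must lie in [0, 1]")
    gt_mask = _as_consensus_mask(gt)
    if tol is None:
        h, w = response.shape
        tol = 0.0075 * float(np.hypot(h, w))
    thinned = non_maxima_suppress(response) if thin else response
    peak = float(response.max()) if response.max() > 0 else 1.0
    thresholds = np.linspace(1.0, 1.0 / n_thresholds, n_thresholds) * peak
    precision = np.zeros(n_thresholds)
    recall = np.zeros(n_thresholds)
    f_scores = np.zeros(n_thresholds)
    for j, level in enumerate(thresholds):
        pred = (thinned >= level).astype(np.float64)
        tp, fp, fn = match_boundaries(pred, gt_mask, tol)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precision[j] = p
        recall[j] = r
        f_scores[j] = f_measure(p, r)
    order = np.argsort(recall, kind="stable")
    r_sorted = recall[order]
    p_sorted = precision[order]
    # extend the curve to R = 0 at the precision of its most conservative point
    r_ext = np.concatenate([[0.0], r_sorted])
    p_ext = np.concatenate([[p_sorted[0] if len(p_sorted) else 0.0], p_sorted])
    ap = float(np.trapezoid(p_ext, r_ext))
    best = int(np.argmax(f_scores))
    return PRCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        f=f_scores,
        ap=ap,
        best_f=float(f_scores[best]),
        best_threshold=float(thresholds[best]),
    )
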