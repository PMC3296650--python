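"""Evaluation helpers for simulation experiments.

Utilities that tie a scan to simulation truth: picking the best region,
sweeping the BIC threshold t_B for classification accuracy, and detection
round-trip metrics.  Used by the examples and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import classify as _classify
from .scan import merge_regions, segmental_metrics

__all__ = [
    "threshold_grid",
    "best_region",
    "max_chromosome_accuracy",
    "max_subject_accuracy",
    "detection_metrics",
    "max_bic",
]


def threshold_grid(windows, n: int = 25) -> np.ndarray:
    """A t_B grid: zero plus quantiles of the positive window BICs."""
    pos = np.array([w.bic for w in windows if w.bic > 0])
    if pos.size == 0:
        return np.array([0.0])
    qs = np.quantile(pos, np.linspace(0.0, 0.98, n - 1))
    return np.unique(np.concatenate([[0.0], qs]))


def best_region(windows, t_B: float = 0.0):
    """The region of interest with the highest BIC, with its windows."""
    rois = merge_regions(windows, t_B)
    if not rois:
        return None, []
    best = max(rois, key=lambda r: r.max_bic)
    return best, [windows[i] for i in best.window_indices]


def max_chromosome_accuracy(windows, orientation, grid=None):
    """Best chromosome-level accuracy over a t_B grid (haplotype pathway)."""
    _, group = best_region(windows)
    if not group:
        return 0.0, 0.0
    grid = threshold_grid(group) if grid is None else grid
    best_acc, best_tb = 0.0, 0.0
    for tb in grid:
        calls = _classify.call_chromosomes(_classify.vote(group, tb))
        if (calls != _classify.NO_CALL).any():
            acc = _classify.accuracy(calls, orientation)
            if acc > best_acc:
                best_acc, best_tb = acc, tb
    return best_acc, best_tb


def max_subject_accuracy(windows, truth_counts, n_subjects, grid=None):
    """Best subject-level inversion-genotype accuracy over a t_B grid."""
    _, group = best_region(windows)
    if not group:
        return 0.0, 0.0
    grid = threshold_grid(group) if grid is None else grid
    best_acc, best_tb = 0.0, 0.0
    for tb in grid:
        calls = _classify.call_subjects(group, tb, n_subjects)
        if (calls != _classify.NO_CALL).any():
            acc = _classify.accuracy(calls, truth_counts)
            if acc > best_acc:
                best_acc, best_tb = acc, tb
    return best_acc, best_tb


def detection_metrics(windows, truth_segment_bp, t_B: float = 0.0):
    """Round-trip detection summary against the true segment.

    Returns (sensitivity, fdr, fraction of fully-contained windows with
    BIC > 0); sensitivity/FDR refer to the best region, or zeros when the
    scan calls nothing.
    """
    roi, _ = best_region(windows, t_B)
    sens, fdr = (0.0, 0.0) if roi is None else segmental_metrics(roi, truth_segment_bp)
    t0, t1 = truth_segment_bp
    contained = [
        w for w in windows if w.left_bp.midpoint_bp >= t0 and w.right_bp.midpoint_bp <= t1
    ]
    frac_pos = float(np.mean([w.bic > 0 for w in contained])) if contained else 0.0
    return sens, fdr, frac_pos


def max_bic(windows) -> float:
    """Largest window BIC of a scan (-inf for an empty scan)."""
    return max((w.bic for w in windows), default=-np.inf)
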