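"""Sliding-window inversion scan.

Candidate breakpoints are gaps between consecutive SNPs (subject to MAF and
missingness filters).  Each candidate left breakpoint is probed with a
single trial segment of fixed physical length — the right breakpoint is the
candidate closest to ``left + window_size`` within a ±25% band — so the
number of windows grows linearly with the number of SNPs.  Every window is
scored with the four-block mixture model (haplotype data directly; genotype
data after local phasing and chromosome pairing), and windows whose BIC
exceeds a threshold are merged into regions of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classify as _classify
from .io import SnpPanel
from .mixture import fit_mixture, fit_null, quartet_from_alleles, score_models
from .phasing import pair_blocks, phase_window, split_blocks

__all__ = [
    "Breakpoint",
    "WindowResult",
    "RegionOfInterest",
    "filter_snps",
    "candidate_breakpoints",
    "enumerate_windows",
    "score_window",
    "scan_panel",
    "merge_regions",
    "segmental_metrics",
]

logger = logging.getLogger("invscan")


@dataclass(frozen=True)
class Breakpoint:
    """A candidate breakpoint between two consecutive SNPs."""

    left_snp_index: int
    right_snp_index: int
    midpoint_bp: float

    @classmethod
    def between(cls, panel: SnpPanel, i: int) -> "Breakpoint":
        return cls(i, i + 1, 0.5 * (panel.positions[i] + panel.positions[i + 1]))


@dataclass
class WindowResult:
    """One scored trial segment.

    ``resp`` holds per-chromosome forward responsibilities (Eq.-style,
    unweighted).  For genotype data, chromosomes 2i/2i+1 belong to included
    subject ``subject_index[i]`` and their labels are window-local.
    """

    left_bp: Breakpoint
    right_bp: Breakpoint
    bic: float
    pi_hat: float
    resp: np.ndarray
    n_used: int
    data_kind: str
    subject_index: np.ndarray | None = None

    @property
    def interval_bp(self) -> tuple[float, float]:
        return (self.left_bp.midpoint_bp, self.right_bp.midpoint_bp)


@dataclass
class RegionOfInterest:
    """Merged overlapping significant windows (coordinates in Mb)."""

    lbp_min: float
    lbp_max: float
    rbp_min: float
    rbp_max: float
    max_bic: float
    inv_freq: float
    ns: int
    window_indices: list = field(default_factory=list)


def filter_snps(panel: SnpPanel, max_missing: float = 0.10) -> SnpPanel:
    """Drop SNPs missing in more than ``max_missing`` of the subjects.

    No-op for haplotype panels.  Raises if nothing survives.
    """
    if panel.data_kind != "genotype":
        return panel
    frac = (panel.matrix < 0).mean(axis=0)
    keep = frac <= max_missing
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_snps: removed %d of %d SNPs (missingness > %g)", n_drop, keep.size, max_missing)
    if not keep.any():
        raise ValueError("all SNPs removed by the missingness filter")
    return panel.subset(keep) if n_drop else panel


def candidate_breakpoints(panel: SnpPanel, maf_min: float = 0.10) -> list[Breakpoint]:
    """Breakpoints between consecutive SNPs where at least one has MAF >= maf_min."""
    if panel.n_snps < 2:
        return []
    maf = panel.maf()
    keep = np.maximum(maf[:-1], maf[1:]) >= maf_min
    return [Breakpoint.between(panel, i) for i in np.flatnonzero(keep)]


def enumerate_windows(
    breakpoints: list[Breakpoint],
    window_size_bp: float,
    tolerance: float = 0.25,
) -> list[tuple[int, int]]:
    """Pair each left breakpoint with the right one spanning ~window_size.

    The chosen right breakpoint minimizes |span − window_size| and must lie
    within ±tolerance·window_size of it; at most one window per left
    breakpoint, hence O(n) windows.
    """
    if window_size_bp <= 0:
        raise ValueError("window_size_bp must be positive")
    mids = np.asarray([b.midpoint_bp for b in breakpoints])
    out = []
    for i, left in enumerate(mids):
        target = left + window_size_bp
        j = int(np.searchsorted(mids, target))
        best = None
        for cand in (j - 1, j):
            if cand <= i or cand >= mids.size:
                continue
            err = abs(mids[cand] - target)
            if best is None or err < best[0]:
                best = (err, cand)
        if best is not None and best[0] <= tolerance * window_size_bp:
            out.append((i, best[1]))
    return out


class _PhaseCache:
    """Per-breakpoint phasing memo for the genotype pathway."""

    def __init__(self, panel, n, tol, max_iter):
        self.panel = panel
        self.n = n
        self.tol = tol
        self.max_iter = max_iter
        self._memo = {}

    def get(self, bp: Breakpoint):
        key = bp.left_snp_index
        if key not in self._memo:
            lo = bp.left_snp_index - self.n + 1
            hi = bp.right_snp_index + self.n
            window = self.panel.matrix[:, lo:hi]
            self._memo[key] = phase_window(window, tol=self.tol, max_iter=self.max_iter)
        return self._memo[key]


def score_window(
    panel: SnpPanel,
    left_bp: Breakpoint,
    right_bp: Breakpoint,
    n: int = 5,
    tol: float = 1e-3,
    max_iter: int = 100,
    _cache: _PhaseCache | None = None,
) -> WindowResult | None:
    """Fit null and mixture models on one trial segment.

    Returns None (with a log entry) when fewer than ``n`` SNPs flank a
    breakpoint or the flanking blocks of the two breakpoints overlap.
    """
    s = panel.n_snps
    if (
        left_bp.left_snp_index - n + 1 < 0
        or right_bp.right_snp_index + n - 1 >= s
        or right_bp.left_snp_index - n < left_bp.right_snp_index + n - 1
    ):
        logger.debug("window at %.0f-%.0f skipped: insufficient flanking SNPs", left_bp.midpoint_bp, right_bp.midpoint_bp)
        return None

    if panel.data_kind == "haplotype":
        li, ri = left_bp.left_snp_index, right_bp.left_snp_index
        mat = panel.matrix
        q = quartet_from_alleles(
            mat[:, li - n + 1 : li + 1],
            mat[:, li + 1 : li + n + 1],
            mat[:, ri - n + 1 : ri + 1],
            mat[:, ri + 1 : ri + n + 1],
        )
        subject_index = None
    else:
        if _cache is None:
            _cache = _PhaseCache(panel, n, tol, max_iter)
        left = _cache.get(left_bp)
        right = _cache.get(right_bp)
        try:
            cb, _ = pair_blocks(left, right, tol=tol, max_iter=max_iter)
        except ValueError:
            logger.debug("window at %.0f-%.0f skipped: too few phased subjects", left_bp.midpoint_bp, right_bp.midpoint_bp)
            return None
        q = split_blocks(cb)
        subject_index = cb.subject_index

    null = fit_null(q)
    alt = fit_mixture(q, null, tol=tol, max_iter=max_iter)
    score = score_models(null, alt, q.m)
    return WindowResult(
        left_bp=left_bp,
        right_bp=right_bp,
        bic=score.bic,
        pi_hat=alt.pi,
        resp=alt.resp_fwd,
        n_used=q.m,
        data_kind=panel.data_kind,
        subject_index=subject_index,
    )


def scan_panel(
    panel: SnpPanel,
    window_size_bp: float,
    n: int = 5,
    maf_min: float = 0.10,
    max_missing: float = 0.10,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> list[WindowResult]:
    """Full scan: filter, enumerate candidate windows, score each one."""
    panel = filter_snps(panel, max_missing)
    bps = candidate_breakpoints(panel, maf_min)
    pairs = enumerate_windows(bps, window_size_bp)
    cache = _PhaseCache(panel, n, tol, max_iter) if panel.data_kind == "genotype" else None
    results = []
    for i, j in pairs:
        wr = score_window(panel, bps[i], bps[j], n=n, tol=tol, max_iter=max_iter, _cache=cache)
        if wr is not None:
            results.append(wr)
    logger.info("scan: %d candidate breakpoints, %d windows scored", len(bps), len(results))
    return results


def _roi_inv_freq(group, t_B):
    """Majority-vote inversion frequency over the windows of one region."""
    w0 = group[0]
    if w0.data_kind == "haplotype":
        calls = _classify.call_chromosomes(_classify.vote(group, t_B))
    else:
        n_subj = max(int(w.subject_index.max()) for w in group if w.subject_index is not None) + 1
        status = _classify.call_subjects(group, t_B, n_subj)
        ok = status != _classify.NO_CALL
        if not ok.any():
            return 0.0
        return float(status[ok].sum() / (2.0 * ok.sum()))
    ok = calls != _classify.NO_CALL
    if not ok.any():
        return 0.0
    return float(np.mean(calls[ok] == _classify.INVERTED))


def merge_regions(windows: list[WindowResult], t_B: float) -> list[RegionOfInterest]:
    """Group significant windows (bic > t_B) into maximal overlapping chains.

    Two windows overlap when their [left midpoint, right midpoint]
    intervals intersect.  The result is ordered by LBPmin and is invariant
    to the input order.
    """
    sig = [(i, w) for i, w in enumerate(windows) if w.bic > t_B]
    sig.sort(key=lambda t: (t[1].left_bp.midpoint_bp, t[1].right_bp.midpoint_bp))
    rois = []
    group, right_max = [], -np.inf
    for idx, w in sig:
        lo, hi = w.interval_bp
        if group and lo > right_max:
            rois.append(_finalize(group, t_B))
            group, right_max = [], -np.inf
        group.append((idx, w))
        right_max = max(right_max, hi)
    if group:
        rois.append(_finalize(group, t_B))
    return rois


def _finalize(group, t_B):
    ws = [w for _, w in group]
    lefts = [w.left_bp.midpoint_bp for w in ws]
    rights = [w.right_bp.midpoint_bp for w in ws]
    return RegionOfInterest(
        lbp_min=min(lefts) / 1e6,
        lbp_max=max(lefts) / 1e6,
        rbp_min=min(rights) / 1e6,
        rbp_max=max(rights) / 1e6,
        max_bic=max(w.bic for w in ws),
        inv_freq=_roi_inv_freq(ws, t_B),
        ns=len(ws),
        window_indices=[i for i, _ in group],
    )


def segmental_metrics(roi: RegionOfInterest, truth_segment_bp) -> tuple[float, float]:
    """Segmental sensitivity and false discovery rate of one region call.

    The called segment is the full extent of the region — the core
    [LBPmax, RBPmin] together with its breakpoint-uncertainty intervals,
    i.e. [LBPmin, RBPmax].  Sensitivity is the fraction of the true segment
    covered; FDR the fraction of the call outside the truth.
    """
    lo = roi.lbp_min * 1e6
    hi = roi.rbp_max * 1e6
    t0, t1 = truth_segment_bp
    called = hi - lo
    if called <= 0:
        return 0.0, 0.0
    inter = max(0.0, min(hi, t1) - max(lo, t0))
    sens = inter / (t1 - t0) if t1 > t0 else 0.0
    fdr = (called - inter) / called
    return float(sens), float(fdr)
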