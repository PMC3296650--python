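"""Four-block linkage mixture model for inversion detection.

A candidate inverted segment is delimited by two breakpoints, each flanked
by a block of N SNPs, giving four categorical block variables B1..B4 per
chromosome (or per subject during local phasing).  Under the null the
population factorizes as the joint of (B1,B2) times the joint of (B3,B4):
linkage crosses each breakpoint but not the segment.  Under the inversion
model a fraction ``pi`` of the sample instead factorizes as (B1,B3) times
(B2,B4): the blocks adjacent to each other in the *inverted* arrangement
travel together.  The two models are fit by maximum likelihood (the
alternative by EM) and compared with a BIC difference; positive values
favor the inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._em import PROB_FLOOR, mixture_em

__all__ = [
    "BlockQuartet",
    "NullFit",
    "MixtureFit",
    "ModelScore",
    "encode_blocks",
    "quartet_from_ints",
    "quartet_from_alleles",
    "fit_null",
    "fit_mixture",
    "responsibilities",
    "score_models",
]

#: incremented whenever both component densities vanish for an observation
#: (responsibility then defaults to 0.5)
ZERO_DENSITY_EVENTS = {"count": 0}


@dataclass
class BlockQuartet:
    """m observations of the four block variables, as dense category codes.

    ``codes`` is an (m, 4) integer matrix; column j takes values in
    ``0 .. K_j - 1``.  ``category_maps[j]`` maps each code back to the
    originating N-SNP allele string.
    """

    codes: np.ndarray
    category_maps: list

    def __post_init__(self):
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] != 4:
            raise ValueError("codes must be an (m, 4) matrix")
        if self.codes.shape[0] < 1:
            raise ValueError("need at least one observation")
        for j in range(4):
            k = len(self.category_maps[j])
            col = self.codes[:, j]
            if col.min() < 0 or col.max() >= k:
                raise ValueError(f"column {j} codes outside 0..{k - 1}")

    @property
    def m(self) -> int:
        return self.codes.shape[0]

    @property
    def n_categories(self) -> tuple:
        return tuple(len(c) for c in self.category_maps)

    def decode(self, column: int, code: int) -> str:
        return self.category_maps[column][code]

    def joint_indices(self):
        """Flattened joint indices for the pairings (1,2), (3,4), (1,3), (2,4)."""
        cached = getattr(self, "_joint_cache", None)
        if cached is not None:
            return cached
        k = self.n_categories
        c = self.codes
        i12 = c[:, 0] * k[1] + c[:, 1]
        i34 = c[:, 2] * k[3] + c[:, 3]
        i13 = c[:, 0] * k[2] + c[:, 2]
        i24 = c[:, 1] * k[3] + c[:, 3]
        object.__setattr__(self, "_joint_cache", (i12, i34, i13, i24))
        return i12, i34, i13, i24


def encode_blocks(block_strings) -> BlockQuartet:
    """Densely encode an (m, 4) collection of N-SNP allele strings.

    All strings within a column must have equal length and contain only the
    characters ``0`` and ``1``.  Codes follow the sorted order of the
    distinct strings, so the encoding is a reproducible bijection.
    """
    arr = np.asarray(block_strings, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("block_strings must be an (m, 4) collection")
    codes = np.empty(arr.shape, dtype=np.int64)
    maps = []
    for j in range(4):
        col = arr[:, j].astype(str)
        lengths = {len(s) for s in col}
        if len(lengths) != 1:
            raise ValueError(f"ragged string lengths in column B{j + 1}")
        for s in col:
            if set(s) - {"0", "1"}:
                raise ValueError(f"non-binary allele string in column B{j + 1}: {s!r}")
        cats, inv = np.unique(col, return_inverse=True)
        codes[:, j] = inv
        maps.append(list(cats))
    return BlockQuartet(codes, maps)


def _dense_ids(values, upper=None):
    """Dense 0..K-1 ids for non-negative integers; bincount-based when cheap."""
    if upper is not None and upper <= (1 << 22):
        present = np.zeros(upper, dtype=bool)
        present[values] = True
        cells = np.flatnonzero(present)
        lookup = np.empty(upper, dtype=np.int64)
        lookup[cells] = np.arange(cells.size)
        return cells, lookup[values]
    return np.unique(values, return_inverse=True)


def quartet_from_ints(columns, n_bits) -> BlockQuartet:
    """Build a quartet from bit-packed block integers (first SNP = high bit)."""
    if np.isscalar(n_bits):
        n_bits = [int(n_bits)] * 4
    codes = np.empty((len(columns[0]), 4), dtype=np.int64)
    maps = []
    for j in range(4):
        vals = np.asarray(columns[j], dtype=np.int64)
        upper = (1 << n_bits[j]) if n_bits[j] <= 22 else None
        cats, inv = _dense_ids(vals, upper)
        codes[:, j] = inv
        maps.append([format(int(v), f"0{n_bits[j]}b") for v in cats])
    return BlockQuartet(codes, maps)


def quartet_from_alleles(b1, b2, b3, b4) -> BlockQuartet:
    """Build a quartet from four (m, N) 0/1 allele matrices."""
    cols = []
    bits = []
    for blk in (b1, b2, b3, b4):
        blk = np.asarray(blk, dtype=np.int64)
        n = blk.shape[1]
        weights = 1 << np.arange(n - 1, -1, -1, dtype=np.int64)
        cols.append(blk @ weights)
        bits.append(n)
    return quartet_from_ints(cols, bits)


@dataclass
class NullFit:
    """Empirical-frequency fit of the no-inversion factorization."""

    n12: np.ndarray
    n34: np.ndarray
    loglik0: float
    k0: int


@dataclass
class MixtureFit:
    """EM fit of the forward/inverted mixture."""

    pi: float
    f12: np.ndarray
    f34: np.ndarray
    r13: np.ndarray
    r24: np.ndarray
    loglik1: float
    resp_fwd: np.ndarray
    n_iter: int
    converged: bool
    support_r13: int
    support_r24: int
    loglik_trace: np.ndarray = field(repr=False, default=None)


@dataclass
class ModelScore:
    """BIC difference favoring the mixture; positive values support an inversion."""

    bic: float
    delta_k: int
    m: int


def fit_null(q: BlockQuartet) -> NullFit:
    """Maximum-likelihood null fit: empirical joints of (B1,B2) and (B3,B4)."""
    k = q.n_categories
    i12, i34, _, _ = q.joint_indices()
    m = q.m
    n12 = np.bincount(i12, minlength=k[0] * k[1]).astype(float) / m
    n34 = np.bincount(i34, minlength=k[2] * k[3]).astype(float) / m
    loglik0 = float(np.sum(np.log(n12[i12])) + np.sum(np.log(n34[i34])))
    k0 = int(np.count_nonzero(n12) - 1 + np.count_nonzero(n34) - 1)
    return NullFit(n12.reshape(k[0], k[1]), n34.reshape(k[2], k[3]), loglik0, k0)


def _scatter_full(dense, cells, size):
    full = np.zeros(size)
    full[cells] = dense
    np.maximum(full, PROB_FLOOR, out=full)
    return full / full.sum()


def _floored(t):
    t = np.maximum(t, PROB_FLOOR)
    return t / t.sum()


def fit_mixture(
    q: BlockQuartet,
    init: NullFit | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_starts: int = 1,
) -> MixtureFit:
    """Fit the mixture model by EM.

    Tables are initialized at the empirical joint distributions of the four
    pairings and ``pi`` at 0.5.  The E-step uses pi-weighted posteriors; the
    reported ``resp_fwd`` follows the unweighted forward responsibility used
    for classification.  If the EM endpoint falls below the null likelihood
    (the null is nested at pi = 0), the null-embedded parameterization is
    returned instead.

    With ``n_starts > 1``, additional EM runs start from deterministic
    pseudo-random Dirichlet tables and the best endpoint is kept; tiny or
    degenerate inputs can have local optima that the empirical start
    misses.  The default single start suffices for population-scale scans.

    The EM itself runs on the observed joint-category support (duplicate
    observations collapsed to weights), which keeps each iteration O(unique
    rows); unseen cells of the full tables receive the probability floor.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if init is None:
        init = fit_null(q)
    k = q.n_categories
    i12, i34, i13, i24 = q.joint_indices()
    # dense ids over the observed cells of each pairing
    u12, c12 = _dense_ids(i12, k[0] * k[1])
    u34, c34 = _dense_ids(i34, k[2] * k[3])
    u13, c13 = _dense_ids(i13, k[0] * k[2])
    u24, c24 = _dense_ids(i24, k[1] * k[3])
    # (c12, c34) identifies the full quartet row: collapse duplicates
    key = c12.astype(np.int64) * len(u34) + c34
    _, row_id = _dense_ids(key, len(u12) * len(u34))
    w = np.bincount(row_id).astype(float)
    first = np.empty(w.size, dtype=np.int64)
    first[row_id[::-1]] = np.arange(row_id.size - 1, -1, -1)
    rows = (c12[first], c34[first], c13[first], c24[first])
    m = q.m

    def empirical(ids, size):
        return _floored(np.bincount(ids, weights=np.full(ids.size, 1.0 / m), minlength=size))

    best = None
    rng = np.random.default_rng(1299709)  # fixed: deterministic extra starts
    for s in range(max(1, n_starts)):
        if s == 0:
            inits = (
                empirical(c12, len(u12)),
                empirical(c34, len(u34)),
                empirical(c13, len(u13)),
                empirical(c24, len(u24)),
            )
            pi0 = 0.5
        else:
            inits = tuple(
                _floored(rng.dirichlet(np.ones(n))) for n in (len(u12), len(u34), len(u13), len(u24))
            )
            pi0 = float(rng.uniform(0.05, 0.95))
        out = mixture_em(*rows, w, *inits, pi0, tol, max_iter)
        if best is None or out[5][-1] > best[5][-1]:
            best = out
    pi, f12d, f34d, r13d, r24d, trace, converged = best
    loglik1 = float(trace[-1])
    support_r13 = len(u13)
    support_r24 = len(u24)

    f12 = _scatter_full(f12d, u12, k[0] * k[1])
    f34 = _scatter_full(f34d, u34, k[2] * k[3])
    r13 = _scatter_full(r13d, u13, k[0] * k[2])
    r24 = _scatter_full(r24d, u24, k[1] * k[3])

    if loglik1 < init.loglik0 - 1e-9:
        # EM found a worse local optimum than the nested null; embed the null.
        pi = 0.0
        f12 = _scatter_full(init.n12.ravel()[u12], u12, k[0] * k[1])
        f34 = _scatter_full(init.n34.ravel()[u34], u34, k[2] * k[3])
        loglik1 = float(np.sum(np.log(f12[i12] * f34[i34])))
        converged = True

    fit = MixtureFit(
        pi=float(pi),
        f12=f12.reshape(k[0], k[1]),
        f34=f34.reshape(k[2], k[3]),
        r13=r13.reshape(k[0], k[2]),
        r24=r24.reshape(k[1], k[3]),
        loglik1=loglik1,
        resp_fwd=None,
        n_iter=len(trace),
        converged=bool(converged),
        support_r13=support_r13,
        support_r24=support_r24,
        loglik_trace=trace,
    )
    fit.resp_fwd = responsibilities(fit, q)
    return fit


def responsibilities(fit: MixtureFit, q: BlockQuartet, weighted: bool = False) -> np.ndarray:
    """Forward responsibilities r0 per observation.

    With ``weighted=False`` (the classification convention) the densities are
    compared unweighted, r0 = P_fwd / (P_fwd + P_inv); with ``weighted=True``
    the mixture weights (1-pi) and pi enter, as in the EM E-step.
    """
    i12, i34, i13, i24 = q.joint_indices()
    pf = fit.f12.ravel()[i12] * fit.f34.ravel()[i34]
    pv = fit.r13.ravel()[i13] * fit.r24.ravel()[i24]
    if weighted:
        pf = (1.0 - fit.pi) * pf
        pv = fit.pi * pv
    denom = pf + pv
    zero = denom <= 0.0
    if np.any(zero):
        ZERO_DENSITY_EVENTS["count"] += int(zero.sum())
        denom = np.where(zero, 1.0, denom)
        pf = np.where(zero, 0.5, pf)
    return pf / denom


def score_models(null: NullFit, alt: MixtureFit, m: int) -> ModelScore:
    """BIC difference 2*(loglik1 - loglik0) - delta_k * ln(m).

    ``delta_k`` counts the extra parameters of the mixture: the inversion
    frequency plus the inverted-subpopulation tables, with table dimension
    taken from the observed category support.
    """
    if m < 2:
        raise ValueError("BIC comparison needs at least 2 observations")
    delta_k = 1 + (alt.support_r13 - 1) + (alt.support_r24 - 1)
    bic = 2.0 * (alt.loglik1 - null.loglik0) - delta_k * np.log(m)
    return ModelScore(bic=float(bic), delta_k=int(delta_k), m=int(m))
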