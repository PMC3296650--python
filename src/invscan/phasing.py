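"""Local phasing of genotype windows around candidate breakpoints.

The genotype pathway needs, for each subject, the two 2N-SNP haplotypes
containing each breakpoint in the middle.  Phasing is done per window by an
EM over multilocus haplotype frequencies (the classical Excoffier-Slatkin
scheme); for each subject the compatible haplotype pair with the highest
posterior is kept, and missing alleles are imputed by the same
maximization.  A first application of the four-block mixture model then
sorts out which left haplotype travels with which right haplotype on the
same chromosome, producing per-chromosome block data for detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._em import enumerate_pairs, enumerate_rows, phase_em
from .mixture import (
    BlockQuartet,
    MixtureFit,
    fit_mixture,
    fit_null,
    quartet_from_ints,
)

__all__ = [
    "MAX_WINDOW_SNPS",
    "PhasedBlock",
    "LocalHaplotypes",
    "ChromosomeBlocks",
    "phase_window",
    "pair_blocks",
    "split_blocks",
    "unpack_bits",
]

#: enumeration bound on the phased window width (2N SNPs)
MAX_WINDOW_SNPS = 16
_MAX_PAIR_COMBOS = 1 << 16


def unpack_bits(values, n_bits: int) -> np.ndarray:
    """Unpack bit-packed haplotypes (first SNP = high bit) to a 0/1 matrix."""
    values = np.asarray(values, dtype=np.int64)
    shifts = np.arange(n_bits - 1, -1, -1, dtype=np.int64)
    return ((values[:, None] >> shifts[None, :]) & 1).astype(np.int8)


@dataclass
class PhasedBlock:
    """Phased 2N-SNP haplotype pairs for one breakpoint window.

    ``hap1``/``hap2`` are bit-packed per subject with ``hap1 <= hap2``
    (canonical order; the chromosome assignment is resolved later by
    :func:`pair_blocks`).  Subjects with no observed genotype in the window
    are flagged ``included=False`` and carry -1 haplotypes.
    """

    hap1: np.ndarray
    hap2: np.ndarray
    posterior: np.ndarray
    included: np.ndarray
    n_sites: int
    converged: bool

    def haplotypes(self) -> tuple[np.ndarray, np.ndarray]:
        return unpack_bits(self.hap1, self.n_sites), unpack_bits(self.hap2, self.n_sites)


@dataclass
class LocalHaplotypes:
    """Per-subject phased pairs for the left and right breakpoint windows."""

    left: PhasedBlock
    right: PhasedBlock

    @property
    def included(self) -> np.ndarray:
        return self.left.included & self.right.included


@dataclass
class ChromosomeBlocks:
    """Per-chromosome 2N-SNP haplotypes around both breakpoints.

    Chromosomes 2i and 2i+1 belong to included subject i (see
    ``subject_index``).  ``hl``/``hr`` are bit-packed; splitting each into
    its two N-SNP halves yields the detection quartet.
    """

    hl: np.ndarray
    hr: np.ndarray
    n: int
    pairing_resp: np.ndarray
    subject_index: np.ndarray

    @property
    def n_chromosomes(self) -> int:
        return self.hl.size


def phase_window(
    genotypes: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PhasedBlock:
    """Phase a genotype window of at most 16 SNPs.

    ``genotypes`` is (n_subjects, width) with codes 0/1/2 and -1 for
    missing.  Haplotype frequencies are fit by EM over all compatible
    haplotype pairs; each subject receives its maximum-posterior pair.
    """
    g = np.ascontiguousarray(genotypes, dtype=np.int8)
    if g.ndim != 2:
        raise ValueError("genotypes must be a 2-D matrix")
    n_s, width = g.shape
    if width > MAX_WINDOW_SNPS:
        raise ValueError(
            f"window of {width} SNPs exceeds the enumerable bound of "
            f"{MAX_WINDOW_SNPS}; use a smaller block size N"
        )
    included = ~np.all(g < 0, axis=1)
    gi = g[included]
    if gi.shape[0] == 0:
        raise ValueError("all subjects missing in the phasing window")

    # collapse identical genotype rows (base-4 key; missing -> digit 3)
    digits = (gi.astype(np.int64)) & 3
    key = digits @ (4 ** np.arange(width - 1, -1, -1, dtype=np.int64))
    urows, first, row_of = np.unique(key, return_index=True, return_inverse=True)

    cap = _MAX_PAIR_COMBOS
    while True:
        buf_a = np.empty(cap, np.int64)
        buf_b = np.empty(cap, np.int64)
        buf_r = np.empty(cap, np.int64)
        cnt = enumerate_rows(gi[first], buf_a, buf_b, buf_r)
        if cnt >= 0:
            break
        cap *= 4
        if cap > (1 << 24):
            raise ValueError("too many ambiguous sites in window to enumerate")
    pair_a = buf_a[:cnt]
    pair_b = buf_b[:cnt]
    pair_row = buf_r[:cnt]
    row_w = np.bincount(row_of, minlength=len(urows)).astype(float)

    haps, inv = np.unique(np.concatenate([pair_a, pair_b]), return_inverse=True)
    a_id = inv[: pair_a.size]
    b_id = inv[pair_a.size :]

    _, best, post, _, converged = phase_em(
        pair_row, a_id, b_id, row_w, len(urows), len(haps), tol, max_iter
    )

    h1 = np.full(n_s, -1, np.int64)
    h2 = np.full(n_s, -1, np.int64)
    posterior = np.full(n_s, np.nan)
    sel = best[row_of]
    h1[included] = pair_a[sel]
    h2[included] = pair_b[sel]
    posterior[included] = post[row_of]
    return PhasedBlock(h1, h2, posterior, included, width, bool(converged))


def pair_blocks(
    left: PhasedBlock,
    right: PhasedBlock,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[ChromosomeBlocks, MixtureFit]:
    """Resolve the chromosome pairing of left and right phased blocks.

    The mixture model is fit on the subject-level quartet (B1,B2,B3,B4) =
    (L1, R1, R2, L2); a subject whose forward responsibility is >= 0.5 keeps
    the pairing (L1,R1)/(L2,R2), otherwise (L1,R2)/(L2,R1).  Subjects
    homozygous on either side are pairing-invariant and fall on the
    deterministic default.
    """
    if left.hap1.size != right.hap1.size:
        raise ValueError("left and right blocks must cover the same subjects")
    included = left.included & right.included
    idx = np.flatnonzero(included)
    if idx.size < 2:
        raise ValueError("need at least 2 phased subjects to resolve pairing")

    l1, l2 = left.hap1[idx], left.hap2[idx]
    r1, r2 = right.hap1[idx], right.hap2[idx]
    q = quartet_from_ints([l1, r1, r2, l2], [left.n_sites, right.n_sites, right.n_sites, left.n_sites])
    fit = fit_mixture(q, fit_null(q), tol=tol, max_iter=max_iter)
    r0 = fit.resp_fwd
    keep = r0 >= 0.5  # forward pairing (L1,R1)/(L2,R2); ties -> default

    n_c = 2 * idx.size
    hl = np.empty(n_c, np.int64)
    hr = np.empty(n_c, np.int64)
    hl[0::2] = l1
    hl[1::2] = l2
    hr[0::2] = np.where(keep, r1, r2)
    hr[1::2] = np.where(keep, r2, r1)
    cb = ChromosomeBlocks(
        hl=hl,
        hr=hr,
        n=left.n_sites // 2,
        pairing_resp=r0,
        subject_index=idx,
    )
    return cb, fit


def split_blocks(cb: ChromosomeBlocks) -> BlockQuartet:
    """Split per-chromosome haplotypes into the detection quartet.

    B1/B2 are the N-SNP halves flanking the left breakpoint, B3/B4 those
    flanking the right breakpoint; m equals the chromosome count.
    """
    n = cb.n
    mask = (1 << n) - 1
    return quartet_from_ints(
        [cb.hl >> n, cb.hl & mask, cb.hr >> n, cb.hr & mask],
        [n, n, n, n],
    )
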