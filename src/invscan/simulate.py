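"""Synthetic populations carrying a polymorphic inversion.

The generator emulates the linkage signature that suppressed recombination
between orientations leaves in SNP data, without running a coalescent
engine.  Chromosomes are mosaics of founder haplotypes (free recombination
within an orientation and everywhere outside the inverted segment).  The
forward orientation is treated as the old, ancestral arrangement: its
founders are drawn from the base allele-frequency spectrum both inside and
outside the segment.  The inverted orientation is a younger clade with a
single ancestral haplotype for the inverted segment: its founders are
partial-redraw copies of that ancestor, so inverted chromosomes share a
recognizable multi-SNP haplotype across the whole segment.  A configurable
number of divergence sites is fixed between the two orientations.  SNP
coordinates are never reversed inside the segment: arrays report
reference-strand positions regardless of orientation, and the detection
signal is linkage, not coordinate order.

Defaults are calibrated to the summary statistics of invertFREGENE-style
panels: ~0.33 kb/SNP density and a median per-SNP heterozygous fraction
around 0.34 on a 2 Mb segment.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .io import SnpPanel

__all__ = [
    "SimConfig",
    "SimTruth",
    "SummaryStats",
    "simulate_population",
    "simulate_null",
    "summary_stats",
    "write_truth",
    "write_config",
]

FORWARD = 0
INVERTED = 1


@dataclass
class SimConfig:
    """Parameters of one simulated population.

    Lengths are in base pairs; ``snp_spacing_kb`` is the mean inter-SNP
    distance.  ``divergence_mutations`` counts sites fixed between the two
    orientations inside the segment; ``background_mutation_diversity`` is
    the per-site probability that an inverted-clade founder redraws its
    allele from the base spectrum (within-clade drift/mutation diversity).
    """

    segment_length_bp: int = 2_000_000
    inv_start_bp: int = 750_000
    inv_end_bp: int = 1_250_000
    inv_freq: float = 0.4
    n_subjects: int = 1000
    snp_spacing_kb: float = 0.33
    divergence_mutations: int = 40
    recomb_rate_per_bp: float = 1e-5
    background_mutation_diversity: float = 0.2
    seed: int = 0
    n_founders: int = 8
    flip_rate: float = 5e-4

    def __post_init__(self):
        if not (0 <= self.inv_start_bp < self.inv_end_bp <= self.segment_length_bp):
            raise ValueError("need 0 <= inv_start < inv_end <= segment_length")
        if not (0.0 <= self.inv_freq <= 1.0):
            raise ValueError("inv_freq must lie in [0, 1]")
        if self.snp_spacing_kb <= 0:
            raise ValueError("snp_spacing_kb must be positive")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


@dataclass
class SimTruth:
    """Per-chromosome orientation labels (0 forward, 1 inverted) and the true segment."""

    orientation: np.ndarray
    segment: tuple[int, int]

    def subject_counts(self) -> np.ndarray:
        """Number of inverted chromosomes per subject (0, 1 or 2)."""
        o = self.orientation
        return (o[0::2] + o[1::2]).astype(np.int8)


def _base_maf(rng, size):
    # skewed toward low MAF; together with the finite founder pool this
    # yields a median per-SNP heterozygous fraction ~0.34
    return 0.05 + 0.45 * rng.random(size) ** 1.4


def _positions(rng, cfg):
    n_expect = int(cfg.segment_length_bp / (cfg.snp_spacing_kb * 1000))
    n_draw = int(n_expect * 1.3) + 100
    gaps = rng.exponential(cfg.snp_spacing_kb * 1000, n_draw)
    pos = 1 + np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
    pos = pos[pos <= cfg.segment_length_bp]
    if pos.size < 2:
        raise ValueError("segment too short for the requested SNP spacing")
    return pos


def simulate_population(cfg: SimConfig):
    """Generate one population; returns (haplotype panel, genotype panel, truth).

    The haplotype panel has 2*n_subjects rows (chromosomes 2i and 2i+1
    belong to subject i); the genotype panel is the per-subject allele sum
    with the usual 0/1/2 encoding.  Output is deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_c = 2 * cfg.n_subjects
    if 0 < cfg.inv_freq and cfg.inv_freq * n_c < 1:
        warnings.warn("inv_freq * 2n < 1: the inversion may be absent from the sample")

    pos = _positions(rng, cfg)
    s = pos.size
    maf = _base_maf(rng, s)
    p = np.where(rng.random(s) < 0.5, maf, 1.0 - maf)

    inside = (pos >= cfg.inv_start_bp) & (pos <= cfg.inv_end_bp)
    nf = cfg.n_founders

    # shared founder pool; forward chromosomes draw from it everywhere
    founders_fwd = rng.random((nf, s), dtype=np.float32) < p.astype(np.float32)

    has_inv = cfg.inv_freq > 0
    founders_inv = founders_fwd
    div_idx = np.empty(0, np.int64)
    if has_inv:
        inside_idx = np.flatnonzero(inside)
        n_div = min(cfg.divergence_mutations, inside_idx.size)
        div_idx = np.sort(rng.choice(inside_idx, n_div, replace=False))
        # single ancestral haplotype of the inverted clade
        ancestor = rng.random(s, dtype=np.float32) < p.astype(np.float32)
        redraw = rng.random((nf, s), dtype=np.float32) < cfg.background_mutation_diversity
        redrawn = rng.random((nf, s), dtype=np.float32) < p.astype(np.float32)
        founders_inv = np.where(redraw, redrawn, ancestor[None, :])
        # orientation-fixed sites
        founders_inv[:, div_idx] = True
        founders_fwd = founders_fwd.copy()
        founders_fwd[:, div_idx] = False
        # outside the segment both orientations share the forward pool
        founders_inv[:, ~inside] = founders_fwd[:, ~inside]

    orientation = (rng.random(n_c) < cfg.inv_freq).astype(np.int8)

    # founder mosaic: switch probability per inter-SNP gap
    gaps = np.diff(pos, prepend=pos[0])
    switch_p = (1.0 - np.exp(-cfg.recomb_rate_per_bp * gaps)).astype(np.float32)
    sw = rng.random((n_c, s), dtype=np.float32) < switch_p[None, :]
    sw[:, 0] = True
    tract = np.cumsum(sw, axis=1, dtype=np.int32) - 1
    max_tracts = int(tract[:, -1].max()) + 1
    fid = rng.integers(0, nf, size=(n_c, max_tracts), dtype=np.int16)
    founder_of = np.take_along_axis(fid, tract, axis=1)

    cols = np.broadcast_to(np.arange(s), (n_c, s))
    hap = founders_fwd[founder_of, cols]
    if has_inv:
        inv_rows = orientation == INVERTED
        hap[inv_rows] = founders_inv[founder_of[inv_rows], cols[inv_rows]]

    if cfg.flip_rate > 0:
        flips = rng.random((n_c, s), dtype=np.float32) < cfg.flip_rate
        if div_idx.size:
            flips[:, div_idx] = False
        hap ^= flips
    hap = hap.astype(np.int8)

    genotypes = hap[0::2] + hap[1::2]

    ids = [f"snp{j + 1}" for j in range(s)]
    chrom_ids = [f"chr{i}" for i in range(n_c)]
    subj_ids = [f"subj{i}" for i in range(cfg.n_subjects)]
    hap_panel = SnpPanel(positions=pos, ids=ids, data_kind="haplotype", matrix=hap, sample_ids=chrom_ids)
    geno_panel = SnpPanel(positions=pos, ids=ids, data_kind="genotype", matrix=genotypes, sample_ids=subj_ids)
    truth = SimTruth(orientation=orientation, segment=(cfg.inv_start_bp, cfg.inv_end_bp))
    return hap_panel, geno_panel, truth


def simulate_null(cfg: SimConfig):
    """Population without an inversion: exchangeable chromosomes, no divergence."""
    cfg0 = dataclasses.replace(cfg, inv_freq=0.0, divergence_mutations=0)
    return simulate_population(cfg0)


@dataclass
class SummaryStats:
    density_kb_per_snp: float
    median_het_fraction: float
    r2_distance_kb: np.ndarray
    r2_mean: np.ndarray


def summary_stats(panel: SnpPanel, max_pairs: int = 20000, seed: int = 0) -> SummaryStats:
    """Density (kb/SNP), per-SNP heterozygous fraction, and an r^2-by-distance profile."""
    pos = panel.positions
    if pos.size < 2:
        raise ValueError("need at least 2 SNPs")
    density = (pos[-1] - pos[0]) / 1000.0 / pos.size

    mat = panel.matrix
    if panel.data_kind == "genotype":
        valid = mat >= 0
        het = np.where(valid, mat == 1, False).sum(axis=0) / np.maximum(valid.sum(axis=0), 1)
        alle = np.where(mat >= 0, mat, 0).astype(np.float64) / 2.0
    else:
        q = mat.mean(axis=0)
        het = 2.0 * q * (1.0 - q)
        alle = mat.astype(np.float64)
    median_het = float(np.median(het))

    rng = np.random.default_rng(seed)
    i = rng.integers(0, pos.size, max_pairs)
    j = rng.integers(0, pos.size, max_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    x = alle[:, i]
    y = alle[:, j]
    xm = x - x.mean(axis=0)
    ym = y - y.mean(axis=0)
    denom = np.sqrt((xm**2).sum(axis=0) * (ym**2).sum(axis=0))
    ok = denom > 0
    r2 = np.zeros(i.size)
    r2[ok] = ((xm * ym).sum(axis=0)[ok] / denom[ok]) ** 2
    dist = np.abs(pos[i] - pos[j]) / 1000.0

    bins = np.array([0, 5, 10, 20, 50, 100, 200, 500, 2000], dtype=float)
    centers = 0.5 * (bins[:-1] + bins[1:])
    means = np.full(centers.size, np.nan)
    which = np.digitize(dist, bins) - 1
    for b in range(centers.size):
        sel = which == b
        if sel.any():
            means[b] = r2[sel].mean()
    return SummaryStats(float(density), median_het, centers, means)


def write_truth(truth: SimTruth, path) -> None:
    """Truth TSV: chromosome_id, orientation (forward/inverted)."""
    from .io import atomic_write

    lines = ["chromosome_id\torientation"]
    for i, o in enumerate(truth.orientation):
        lines.append(f"chr{i}\t{'inverted' if o else 'forward'}")
    atomic_write(path, "\n".join(lines) + "\n")


def write_config(cfg: SimConfig, path) -> None:
    """JSON sidecar of the generator parameters."""
    from .io import atomic_write

    atomic_write(path, json.dumps(dataclasses.asdict(cfg), indent=2) + "\n")
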