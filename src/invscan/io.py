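"""Panel formats and result writers.

Two input formats are supported: a plain TSV dialect (first header row:
data kind followed by SNP ids; second header row: ``pos`` followed by
1-based physical positions; then one row per chromosome of 0/1 alleles or
one row per subject of 0/1/2/NA genotype codes, each prefixed with a sample
id) and a VCF subset (biallelic SNVs, GT field; phased pipes yield a
haplotype panel, unphased slashes a genotype panel).

All writes go through a temp-file + rename so partially written output is
never observed.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SnpPanel",
    "read_panel",
    "write_panel",
    "write_roi_table",
    "write_calls",
    "atomic_write",
]

logger = logging.getLogger("invscan")

MISSING = -1


@dataclass
class SnpPanel:
    """SNP matrix with physical coordinates.

    ``matrix`` is chromosomes x SNPs of {0,1} for haplotype data or
    subjects x SNPs of {0,1,2,-1} for genotype data; positions are 1-based
    base pairs, strictly increasing.
    """

    positions: np.ndarray
    ids: list
    data_kind: str
    matrix: np.ndarray
    sample_ids: list

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.data_kind not in ("haplotype", "genotype"):
            raise ValueError(f"unknown data_kind {self.data_kind!r}")
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.positions.size:
            raise ValueError("matrix width must equal the number of positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        hi = self.matrix.max(initial=0)
        if self.data_kind == "haplotype" and (hi > 1 or self.matrix.min(initial=0) < 0):
            raise ValueError("haplotype matrix must contain only 0/1 alleles")
        if self.data_kind == "genotype" and hi > 2:
            raise ValueError("genotype codes must be 0/1/2 or missing")

    @property
    def n_snps(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset(self, snp_mask) -> "SnpPanel":
        snp_mask = np.asarray(snp_mask)
        return SnpPanel(
            positions=self.positions[snp_mask],
            ids=[i for i, keep in zip(self.ids, snp_mask) if keep] if len(self.ids) else [],
            data_kind=self.data_kind,
            matrix=self.matrix[:, snp_mask],
            sample_ids=self.sample_ids,
        )

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of allele 1 (genotype missing values excluded)."""
        if self.data_kind == "haplotype":
            return self.matrix.mean(axis=0)
        valid = self.matrix >= 0
        tot = np.maximum(valid.sum(axis=0), 1)
        return np.where(valid, self.matrix, 0).sum(axis=0) / (2.0 * tot)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)


def atomic_write(path, text: str) -> None:
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_panel(panel: SnpPanel, path) -> None:
    lines = [panel.data_kind + "\t" + "\t".join(panel.ids)]
    lines.append("pos\t" + "\t".join(str(p) for p in panel.positions))
    for sid, row in zip(panel.sample_ids, panel.matrix):
        vals = "\t".join("NA" if v < 0 else str(int(v)) for v in row)
        lines.append(f"{sid}\t{vals}")
    atomic_write(path, "\n".join(lines) + "\n")


def _read_tsv(path) -> SnpPanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        posline = fh.readline().rstrip("\n").split("\t")
    kind = header[0]
    if kind not in ("haplotype", "genotype"):
        raise ValueError(
            f"first header cell must be 'haplotype' or 'genotype', got {kind!r}"
        )
    ids = header[1:]
    positions = np.asarray(posline[1:], dtype=np.int64)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    df = pd.read_csv(path, sep="\t", skiprows=2, header=None, na_values="NA")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    mat = np.where(np.isnan(mat), MISSING, mat).astype(np.int8)
    return SnpPanel(positions, ids, kind, mat, sample_ids)


def _read_vcf(path) -> SnpPanel:
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    positions, ids, rows = [], [], []
    phased_mode = None
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        phased = all(g[2] for g in gts)
        unphased = all(not g[2] for g in gts)
        if not (phased or unphased):
            raise ValueError(f"mixed phased/unphased genotypes at record {var.ID or var.POS}")
        this_mode = "haplotype" if phased else "genotype"
        if phased_mode is None:
            phased_mode = this_mode
        elif phased_mode != this_mode:
            raise ValueError(f"mixed phased/unphased records; first offender at {var.ID or var.POS}")
        if phased_mode == "haplotype":
            alleles = []
            for g in gts:
                if g[0] < 0 or g[1] < 0:
                    raise ValueError(f"missing allele in phased record at {var.ID or var.POS}")
                alleles.extend([g[0], g[1]])
            rows.append(alleles)
        else:
            codes = []
            for g in gts:
                codes.append(MISSING if (g[0] < 0 or g[1] < 0) else g[0] + g[1])
            rows.append(codes)
        positions.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if n_skipped:
        logger.info("skipped %d multi-allelic/non-SNV records", n_skipped)
    mat = np.asarray(rows, dtype=np.int8).T
    if phased_mode == "haplotype":
        sample_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    else:
        sample_ids = samples
    return SnpPanel(np.asarray(positions, np.int64), ids, phased_mode, mat, sample_ids)


def read_panel(path, format: str = "tsv") -> SnpPanel:
    """Read a panel from TSV or VCF; see the module docstring for the dialects."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def write_roi_table(rois, window_size_bp: float, path) -> None:
    """Regions of interest, one per row.

    Columns: window (Mb), LBPmin, LBPmax, RBPmin, RBPmax (Mb, 5 decimals),
    MaxBic (2 decimals), invFreq, Ns.
    """
    lines = ["window\tLBPmin\tLBPmax\tRBPmin\tRBPmax\tMaxBic\tinvFreq\tNs"]
    w = window_size_bp / 1e6
    for r in rois:
        lines.append(
            f"{w:g}\t{r.lbp_min:.5f}\t{r.lbp_max:.5f}\t{r.rbp_min:.5f}\t{r.rbp_max:.5f}"
            f"\t{r.max_bic:.2f}\t{r.inv_freq:.2f}\t{r.ns}"
        )
    atomic_write(path, "\n".join(lines) + "\n")


def write_calls(calls, path) -> None:
    """Classification TSV: id, status, r0I (or inverted-chromosome count), n_windows_used, t_B."""
    lines = ["id\tstatus\tr0I\tn_windows_used\tt_B"]
    for c in calls:
        r0 = c.get("r0I")
        r0s = "NA" if r0 is None or (isinstance(r0, float) and np.isnan(r0)) else f"{r0:.4f}"
        lines.append(f"{c['id']}\t{c['status']}\t{r0s}\t{c['n_windows_used']}\t{c['t_B']:g}")
    atomic_write(path, "\n".join(lines) + "\n")
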