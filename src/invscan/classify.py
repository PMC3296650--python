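"""Chromosome- and subject-level inversion calls.

Each scanned window yields per-chromosome forward responsibilities.  Calls
aggregate windows whose BIC exceeds a threshold t_B by majority vote: for
haplotype data the vote runs per chromosome (labels are consistent across
windows); for genotype data, window-level phasing makes chromosome labels
arbitrary across windows, so the vote aggregates each subject's unordered
pair of chromosome calls (the inverted-chromosome count 0/1/2), which is
label-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FORWARD",
    "INVERTED",
    "NO_CALL",
    "VoteResult",
    "vote",
    "call_chromosome",
    "call_chromosomes",
    "call_subjects",
    "accuracy",
    "inversion_frequency",
    "STATUS_NAMES",
]

FORWARD = 0
INVERTED = 1
NO_CALL = -1

STATUS_NAMES = {0: "hom_ref", 1: "het_inv", 2: "hom_inv", NO_CALL: "no_call"}


@dataclass
class VoteResult:
    """Aggregated forward responsibility r0^I per chromosome at threshold t_B."""

    r0I: np.ndarray
    n_windows_used: int
    t_B: float


def _qualifying(windows, t_B):
    return [w for w in windows if w.bic > t_B]


def vote(windows, t_B: float) -> VoteResult:
    """Majority vote over windows with bic > t_B (haplotype pathway).

    r0^I_i is the fraction of qualifying windows in which chromosome i's
    forward responsibility exceeds 0.5 (both Heaviside steps are strict).
    Chromosomes are uncallable (NaN) when no window qualifies.
    """
    qual = _qualifying(windows, t_B)
    if not qual:
        n = windows[0].resp.size if windows else 0
        return VoteResult(np.full(n, np.nan), 0, t_B)
    votes = np.stack([(w.resp > 0.5).astype(float) for w in qual])
    return VoteResult(votes.mean(axis=0), len(qual), t_B)


def call_chromosome(r0I: float) -> int:
    """Single chromosome call: inverted iff r0^I < 0.5 (ties are forward)."""
    if np.isnan(r0I):
        return NO_CALL
    return INVERTED if r0I < 0.5 else FORWARD


def call_chromosomes(v: VoteResult) -> np.ndarray:
    out = np.full(v.r0I.size, NO_CALL, np.int8)
    ok = ~np.isnan(v.r0I)
    out[ok] = np.where(v.r0I[ok] < 0.5, INVERTED, FORWARD)
    return out


def call_subjects(windows, t_B: float, n_subjects: int) -> np.ndarray:
    """Subject-level inversion genotype (genotype pathway).

    Per qualifying window, a subject's inverted-chromosome count c_w in
    {0,1,2} is taken from its two chromosomes' responsibilities (inverted
    iff r0 < 0.5); the call is the count with the most window votes, ties
    resolved toward the smaller count (conservative toward the reference).
    Subjects in no qualifying window are NO_CALL.
    """
    qual = _qualifying(windows, t_B)
    counts = np.zeros((n_subjects, 3), np.int64)
    for w in qual:
        inv = (w.resp < 0.5).astype(np.int8)
        c = inv[0::2] + inv[1::2]
        sidx = w.subject_index if w.subject_index is not None else np.arange(c.size)
        np.add.at(counts, (sidx, c.astype(np.int64)), 1)
    out = np.full(n_subjects, NO_CALL, np.int8)
    seen = counts.sum(axis=1) > 0
    # argmax returns the lowest index on ties -> conservative tie rule
    out[seen] = np.argmax(counts[seen], axis=1).astype(np.int8)
    return out


def accuracy(calls, truth) -> float:
    """Fraction of callable individuals whose status matches truth exactly."""
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must be aligned")
    ok = calls != NO_CALL
    if not ok.any():
        raise ValueError("no callable individuals")
    return float(np.mean(calls[ok] == truth[ok]))


def inversion_frequency(chromosome_calls) -> float:
    """Fraction of callable chromosomes called inverted."""
    calls = np.asarray(chromosome_calls)
    ok = calls != NO_CALL
    if not ok.any():
        raise ValueError("no callable chromosomes")
    return float(np.mean(calls[ok] == INVERTED))
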