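# Methods

## The inversion model

A chromosomal inversion segregating in a population suppresses
recombination between the two orientations inside the inverted segment.
In SNP data this leaves a linkage signature: alleles inside the segment
stay associated with the orientation on which they arose, so blocks of
SNPs flanking the two breakpoints are coupled *across* the segment in a
way that depends on orientation.

`invscan` tests a candidate segment, delimited by a left and a right
breakpoint (each a gap between two consecutive SNPs), using four block
variables per chromosome: B1 and B2 are the N-SNP haplotype blocks
immediately left and right of the left breakpoint, B3 and B4 those around
the right breakpoint.  Each block is treated as a categorical variable
over its observed allele strings.

Under the **null** (no inversion) the population density factorizes over
the two breakpoints,

    P_fwd(x) = n12(B1,B2) * n34(B3,B4),

whose maximum-likelihood fit is the pair of empirical joint tables.  Under
the **inversion model** the sample is a mixture: a fraction `pi` of
chromosomes carries the inverted arrangement, in which the blocks adjacent
in the *inverted* coordinate system travel together,

    P(x) = (1 - pi) * f12(B1,B2) f34(B3,B4) + pi * r13(B1,B3) r24(B2,B4).

The key property is that the null cannot represent any dependence between
the left pair and the right pair, while the mixture captures exactly the
cross-segment coupling an inversion creates through the latent orientation.

### EM fit

The mixture is fit by EM over the categorical tables and `pi`:

- *initialization*: all four tables start at the empirical joint
  distributions of their pairings; `pi` starts at 0.5;
- *E-step*: standard weighted posteriors
  `w_i = pi P_inv / ((1-pi) P_fwd + pi P_inv)`;
- *M-step*: weighted empirical tables, renormalized;
- *flooring*: table cells below 1e-12 are floored and the table
  renormalized, so unseen categories never produce infinite
  log-likelihoods and EM cannot lock a component's support;
- *convergence*: absolute log-likelihood change below `tol` (default
  1e-6, at most 1000 iterations).  Duplicate observations are collapsed
  to weights first, so one iteration costs O(unique rows).

Two guarantees are enforced rather than assumed.  First, the
log-likelihood trace is monotone (a property test asserts it).  Second,
because the null is nested in the mixture at `pi = 0`, a fit whose
endpoint falls below the null log-likelihood has demonstrably converged to
an inferior local optimum; in that case the null-embedded parameterization
is returned, so `loglik1 >= loglik0` always holds.

On population-scale inputs the empirical-initialization single start is
reliable (and is what the scan uses).  On tiny or degenerate inputs — a
handful of observations with arbitrary category patterns — the likelihood
surface has real local optima, and `fit_mixture(n_starts=k)` adds
deterministic Dirichlet-initialized restarts; the oracle-equivalence test
runs with `n_starts=8` against an independent grid/multi-start maximizer.

### Responsibilities and BIC

Two responsibility conventions exist: the pi-weighted posterior used
inside EM, and the unweighted density ratio

    r0 = P_fwd / (P_fwd + P_inv)

used for all reported classifications (ties at 0.5 count as forward).
Both are available from `responsibilities(..., weighted=...)`.

Model choice uses a BIC difference,

    BIC = 2 (loglik1 - loglik0) - delta_k ln m,

with `delta_k = 1 + (support(r13) - 1) + (support(r24) - 1)` counted from
the observed joint-category supports; positive BIC favors the inversion.
Counting parameters by observed support keeps the penalty finite and
data-driven for sparse categorical tables.

## Genotype pathway: local phasing and pairing

Unphased genotypes are handled in two steps per window.

1. **Window phasing.** The 2N SNPs around each breakpoint (N on each
   side; 2N <= 16 so the haplotype space is enumerable) are phased by EM
   over multilocus haplotype frequencies (Excoffier–Slatkin): all
   haplotype pairs compatible with a subject's genotypes (including
   missing sites) are enumerated, frequencies fit, and each subject
   assigned its maximum-posterior pair; missing alleles are imputed by the
   same maximization.  Phasing uncertainty is not propagated further.
2. **Chromosome pairing.** Window phasing cannot say which left-window
   haplotype lies on the same chromosome as which right-window haplotype.
   This is resolved by a first application of the same mixture model with
   B = (L1, R1, R2, L2) and m = number of subjects: each subject keeps
   the pairing (L1,R1)/(L2,R2) when its forward responsibility is >= 0.5
   and the crossed pairing otherwise.  Subjects homozygous on either side
   are pairing-invariant and fall deterministically on the default.

The per-chromosome blocks are then split at the breakpoints and scored by
a second mixture fit with m = 2 x subjects, exactly as for phased input.
On already-phased data the pathway reduces to block splitting.

## The scan

Candidate breakpoints are consecutive-SNP gaps that survive two filters:
SNPs missing in more than 10% of subjects are dropped, and a breakpoint is
kept only if at least one of its two SNPs has MAF >= 10%.  Each candidate
left breakpoint is probed with a single fixed-length trial segment — the
right breakpoint closest to `left + window_size`, accepted within ±25% of
the window size — giving O(n) windows.  A window needs N SNPs on each
side of both breakpoints, and its inner blocks must not overlap.

Windows with BIC above a threshold `t_B` are merged into regions of
interest: maximal chains of windows whose [left midpoint, right midpoint]
intervals overlap.  A region reports the Mb bounds of its windows' left
breakpoints (LBPmin, LBPmax) and right breakpoints (RBPmin, RBPmax), the
maximum BIC, the window count Ns, and the majority-vote inversion
frequency.  The called segment consists of the core [LBPmax, RBPmin] plus
the two breakpoint-uncertainty intervals; segmental sensitivity and FDR
are computed on that full extent [LBPmin, RBPmax], since with a probe
window shorter than the inversion only fully-contained windows fire and
the core systematically undercovers the truth.

The scan stage runs its EM fits at `tol = 1e-3`, `max_iter = 100` (and
phasing likewise): window-level quantities — BIC values in the tens to
thousands and binary pairing/classification decisions — are insensitive
to log-likelihood refinements below these levels, and the looser setting
roughly halves scan time.  Library defaults for direct `fit_mixture`
calls remain strict.

## Classification

For a threshold `t_B`, each chromosome's aggregated forward
responsibility is the fraction of qualifying windows (BIC > t_B, both
Heaviside steps strict) in which its window responsibility exceeds 0.5;
a chromosome is called inverted when this falls below 0.5.  For genotype
data, chromosome labels are window-local (each window re-phases), so the
subject vote aggregates the label-invariant count of inverted chromosomes
c_w in {0,1,2} per window; the call is the count with most votes, ties
resolved toward the smaller count.  Subjects or chromosomes with no
qualifying window are explicit no-calls and are excluded from (but
reported alongside) accuracy figures.

`t_B` is a user choice.  When truth is known for a subset, pick the value
maximizing accuracy on it; otherwise examine call stability across a grid
(`evaluate.threshold_grid`).  On simulations, accuracy typically rises
with `t_B` until too few windows remain.

## The synthetic-population generator

The generator reproduces the linkage structure the detector consumes, not
genealogies.  Chromosomes are founder-haplotype mosaics:

- SNP positions have exponential spacings, mean 0.33 kb (a 2 Mb segment
  carries ~6000 SNPs; density in kb/SNP is the calibration target);
- per-SNP base minor-allele frequencies follow a spectrum skewed toward
  low MAF (0.05 + 0.45 u^1.4), which together with the finite founder
  pool yields a median per-SNP heterozygous fraction near 0.34;
- 8 founder haplotypes per pool, mosaic switch rate 1e-5 per bp: local
  haplotype diversity (5-SNP blocks mostly carry ~8–15 distinct strings)
  and an r² decay scale of tens of kb, comparable to dense SNP-array
  data;
- per-site noise flips at rate 5e-4 emulate genotyping error.

Orientation structure: each chromosome is inverted with probability
`pi`.  Outside the inverted segment all chromosomes share one founder
pool (free recombination everywhere, between any orientations).  Inside
the segment the **forward** orientation — the old, ancestral arrangement
— draws from founders at drift equilibrium (the base spectrum), while
the **inverted** orientation is a young single-origin clade: its founders
are copies of one ancestral haplotype, each site independently redrawn
from the base spectrum with probability 0.25 (within-clade
drift/mutation diversity).  A configurable number of divergence sites
(default 40) is fixed between the orientations and never redrawn.
Mosaics never cross pools, which is exactly the suppression of
recombination between orientations; SNP order is *not* reversed inside
the segment, since arrays report reference-strand coordinates regardless
of orientation and the detection signal is linkage, not coordinate order.

An earlier symmetric variant (both orientations as low-diversity copies
of two ancestors differing only at divergence sites) was rejected: with
divergence sites sparse, most 5-SNP blocks carried no orientation
information and contained windows rarely reached positive BIC, contrary
to the single-inversion scan behaviour the generator must emulate.

What the generator does *not* emulate: coalescent genealogies and
age-dependent clade structure (accuracy decay for very old, high-frequency
inversions is only crudely mirrored by the within-clade diversity
parameter), ascertainment bias of real arrays, population stratification,
and genotyping missingness patterns (missing data enters tests through
hand-built fixtures instead).  Passing tests therefore demonstrate
correct behaviour on idealized LD structure, not performance on real
cohorts.

## Problem sizes and numerical choices

Simulation studies in the test-suite and the reproduction script use the
canonical conditions — 2 Mb segments, 1000 subjects, a 0.5 Mb inversion
at 0.75–1.25 Mb, window 0.3 Mb (0.6× the inversion length), N = 5 — with
20 replicates per study; module-level unit tests use 1 Mb / 300–500
subject panels, which the package's own diagnostics show retain a clear
detection signal.  Compiled (numba) EM kernels keep a full 1000-subject
genotype scan around 15 s on one core.

Degenerate inputs: a quartet whose observations are all identical yields
`loglik1 = loglik0` and a converged flag; windows with insufficient
flanking SNPs are skipped with a log entry; subjects with no observed
genotype in a phasing window are excluded from that window's quartet;
when both component densities vanish for an observation the
responsibility defaults to 0.5 and a counter increments.  All file writes
are atomic (temp file + rename).
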