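# invscan

Detection and genotyping of polymorphic chromosomal inversions from SNP
panels — phased haplotypes or unphased genotypes — using linkage
disequilibrium alone.

Polymorphic inversions suppress recombination between the inverted and
the standard arrangement, so SNP alleles inside the segment stay coupled
to their orientation of origin.  `invscan` exploits this with a
four-block mixture model.  A candidate segment is bounded by two
breakpoints, each flanked by N-SNP haplotype blocks B1..B4.  Without an
inversion the population factorizes over the breakpoints,
P(x) = n12(B1,B2) · n34(B3,B4); with an inversion at frequency π a latent
fraction of chromosomes instead couples the blocks adjacent in the
inverted arrangement:

    P(x) = (1 − π) · f12(B1,B2) f34(B3,B4) + π · r13(B1,B3) r24(B2,B4)

The mixture is fit by EM and compared with the null by
BIC = 2 Δℓ − Δk·ln m; positive BIC favors an inversion.  A sliding-window
scan probes every candidate breakpoint with one fixed-length trial
segment (O(n) windows), merges significant windows into regions of
interest, and classifies each chromosome — or, via window-local phasing
and chromosome pairing, each subject as hom-ref / het-inv / hom-inv —
by a majority vote of forward responsibilities r0 = P_fwd/(P_fwd+P_inv)
over windows with BIC above a threshold t_B.

A synthetic-population generator (recombination suppressed between
orientations inside the segment, free elsewhere) makes the whole pipeline
testable without external data.  See `docs/methods.md` for the model,
assumptions and numerical choices.

## Worked example

```python
from invscan import (SimConfig, simulate_population, scan_panel,
                     merge_regions, segmental_metrics)

cfg = SimConfig(seed=1)              # 2 Mb, 1000 subjects, inversion
hap, geno, truth = simulate_population(cfg)   # at 0.75-1.25 Mb, pi=0.4

windows = scan_panel(hap, window_size_bp=300_000, n=5)
rois = merge_regions(windows, t_B=0.0)
best = max(rois, key=lambda r: r.max_bic)
print(best.lbp_min, best.lbp_max, best.rbp_min, best.rbp_max,
      round(best.max_bic, 2), round(best.inv_freq, 2), best.ns)
print(segmental_metrics(best, truth.segment))
```

prints

```
0.7518265 0.951344 1.0525435 1.2512255 2176.67 0.41 479
(0.996347, 0.0024539496474762666)
```

i.e. the merged region's left-breakpoint estimates span 0.752–0.951 Mb
and the right-breakpoint estimates 1.053–1.251 Mb, bracketing the true
segment (0.75–1.25 Mb) with segmental sensitivity 0.996 and essentially
no called sequence outside the truth (FDR 0.002); the majority-vote
inversion frequency 0.41 matches the simulated 40%, and 479 overlapping
windows support the call with a peak BIC of ~2177.

The `examples/` scripts walk through each capability: generator
calibration (`simulate_population.py`), haplotype scans
(`detect_inversion.py`), subject genotyping from unphased data
(`genotype_workflow.py`) and null calibration of t_B
(`null_calibration.py`).  A thin CLI wraps the same functions:

```sh
invscan simulate --out-prefix pop --seed 1
invscan scan pop.genotypes.tsv --window-size 0.3Mb --out rois.tsv
invscan classify pop.genotypes.tsv --window-size 0.3Mb --tb 50 --out calls.tsv
```

Panels are plain TSV (or VCF: biallelic SNVs, phased `|` → haplotypes,
unphased `/` → genotypes); region tables follow the
`window LBPmin LBPmax RBPmin RBPmax MaxBic invFreq Ns` schema.

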