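# broodscan

Selection scans for SNP data from hatchery salmon broodlines sampled over
successive generations.

Coho salmon spawn almost exclusively at age three, so a hatchery program
founded from consecutive return years develops several reproductively
isolated **broodlines** that cycle through the same river on a three-year
interval. When such a population is reintroduced into a new habitat, each
broodline is an independent biological replicate of the same natural
experiment: alleles that help in the new environment should rise in
frequency in every broodline, while genetic drift pushes each broodline in
its own random direction. `broodscan` is a toolkit for analysing exactly
this design — diploid biallelic SNP genotypes of broodstock year classes
across ~4 generations — and for validating the analysis on simulated data
with known truth. It is written for population geneticists running genetic
monitoring of reintroduction or supplementation programs.

## What it computes

**QC cascade.** Loci and samples are filtered in a fixed order: non-biallelic
loci and loci with pooled minor allele frequency < 5% out; samples with
< 75% call rate out; loci with < 80% call rate out; then an exact
conditional Hardy–Weinberg test over all remaining samples with
Benjamini–Yekutieli FDR at α = 0.01 (removes null-allele and paralog
artefacts). Removal is strict (`<`), so boundary values survive, and the
report telescopes: every stage's input equals removed + surviving.

**Temporal structure.** Pairwise individual genetic distances use the
codominant genotypic metric of Smouse & Peakall — per locus, half the
squared Euclidean distance between allele-count vectors (AA↔BB = 4,
AA↔AB = 1, …), pairwise-deleted and rescaled for missingness — followed by
classical principal-coordinate analysis (Gower centering of −D²/2). On
data with founder divergence the first two axes separate the broodlines
into the three clusters this design produces.

**Temporal outlier scan.** Per locus and broodline, the tracked-allele
frequency is regressed on generation index (OLS slope *b*, true spacing
kept across a missing generation). The m slopes are ranked against normal
quantiles (Blom positions); a reference line through the paired 5%/95%
quantile points gives each locus an expected slope *e*; the deviation
d = |b − e| is tested with X = d² / mean(d²) against χ²₁, outliers at
p < 0.01. The realized cutoff is a data-dependent multiple of the mean
deviation (≈3.2–4× for well-behaved scans) and is reported per scan.

**FST–heterozygosity outlier scan.** Year classes are treated as
populations; per locus the multi-group Weir–Cockerham (1984) θ and
expected heterozygosity Hₑ = 2p̄(1−p̄) are computed (year classes with
fewer than 8 fish are excluded). A neutral envelope is simulated: the
neutral mean FST is estimated iteratively (trim loci outside a provisional
envelope, recompute), a drift effective size is calibrated to it, 50,000
neutral loci are simulated under multi-generation drift with the observed
group sizes, and per-Hₑ-bin 95% FST quantiles form the envelope. Empirical
upper-tail p-values with Benjamini–Hochberg at FDR 0.1 designate
directional outliers; the lower (balancing) tail is reported separately.

**Consensus and annotation.** A locus significant in ≥ 1 of the (method ×
broodline) tests is a *candidate*; ≥ 2 tests make it *highly significant*;
≥ 2 of 3 methods within one broodline give per-broodline consensus.
"Not tested" is tracked separately from "not significant" so a missing
generation cannot deflate consensus. External Bayesian outlier tables can
be merged as a third method. Candidates are annotated with the three
nearest genes within 100,000 bases (inclusive) of each retained mapped
position (SAM alignments, mapQ ≥ 10, multi-mapping kept; GFF3 genes).

**Simulator.** `broodscan.simdata` generates the whole study design:
source-pool frequencies Uniform(0.05, 0.95), per-broodline founder pools
separated by drift, Wright–Fisher propagation with Ne = 100 per
generation, gametic selection p′ = p(1+s)/(1+ps) at planted loci (same
sign in every broodline), Hardy–Weinberg genotype draws at the year-class
sample sizes (totalling 664 fish, one missing year class, one N = 7 year
class), and beta-distributed per-sample/per-locus missingness — with a
truth table for power and false-positive accounting.

## Worked example

```bash
broodscan pipeline run --seed 42 --out demo/
```

runs simulate → QC → PCoA → temporal scan → FST scan → consensus on the
default simulated study (5,392 loci, 664 fish, 50 loci planted at
s = 0.5). From `demo/manifest.json` and `demo/evaluation.tsv` of that run:

- QC: 5,392 → 5,263 loci (117 below the 5% MAF cutoff, 12 below the 80%
  locus call rate; no sample fell under 75%, no HWE removals — simulated
  genotypes are Hardy–Weinberg draws).
- Temporal scan cutoffs: 4.01×, 3.74×, 6.64× the mean Q–Q deviation for
  broodlines A, B, C at α = 0.01.
- 113 candidate loci, 29 highly significant (≥ 2 tests). Of the 29 highly
  significant, 26 are truly selected and 3 are false positives
  (`evaluation.tsv`, row `tier_highly_significant`), out of 50 planted.
- Venn by method: 81 loci temporal-only, 5 FST-only, 27 by both; by
  broodline, 12 loci are significant in all three broodlines — the
  replicated signals the consensus design exists to find.

Each stage is also available separately (`broodscan simulate`, `qc`,
`pca`, `scan-temporal`, `scan-fst`, `consensus`, `annotate`); see
`broodscan --help`.

As a library:

```python
import numpy as np
from broodscan import SimConfig, simulate_study, run_qc, run_temporal_scan

study = simulate_study(SimConfig(seed=1))
filtered, report = run_qc(study.dataset)
scan = run_temporal_scan(filtered, "C", alpha=0.01)
print(len(scan.outliers), scan.cutoff_multiple_of_mean)
```

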