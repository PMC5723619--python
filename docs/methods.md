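# Methods

This note records the models, parameter choices and numerical decisions
behind `broodscan`, and what the simulation-based validation does and does
not establish.

## Study design and data model

The unit of analysis is a **broodline**: a lineage of hatchery Coho salmon
that spawns on a strict three-year cycle, so consecutive founding return
years (labelled A, B, C) are reproductively isolated from each other. Each
broodline is observed as ~4 successive broodstock year classes
(generations). Genotypes are diploid biallelic SNP calls (samples × loci,
unordered allele-index pairs, missing allowed), with a sidecar table
mapping each sample to brood year, broodline and generation. The tracked
allele is the first-listed allele of each locus (VCF REF / first GenePop
code); every frequency in the package refers to it, and output headers say
so. Coordinates are 1-based inclusive throughout (SAM/GFF convention).

## QC cascade

Order matters and is fixed: (1) drop non-biallelic loci and loci with
pooled MAF < 0.05; (2) drop samples with < 75% of calls over the surviving
loci; (3) drop loci with < 80% of calls over the surviving samples;
(4) exact conditional Hardy–Weinberg test pooling all surviving samples,
Benjamini–Yekutieli step-up at α = 0.01, rejected loci dropped. The HWE
test conditions on the minor-allele count and orders heterozygote
configurations by probability (two-sided); it is exact at the small minor
counts RAD panels produce, where a χ² approximation is unreliable. BY
rather than BH is used because the per-locus HWE statistics are arbitrarily
dependent. The effective threshold (largest rejected raw p) is reported
rather than hard-coded, since it depends on the locus count entering stage
4. Removal is strict inequality everywhere, so values exactly at a
threshold survive; a regression test pins this and the stage order.

## Distances and ordination

Individual distances are the squared codominant-genotypic distance
(Smouse–Peakall): per locus, ½‖c₁ − c₂‖² between allele-count vectors.
Missing data are handled by pairwise deletion with rescaling by
(total loci / shared called loci). The alternative — imputing each missing
call with a pooled mean frequency — would leak frequency information
across broodlines and shrink between-cluster distances, so it is not used.
Principal coordinates are computed directly (Gower double-centering of
−D²/2, symmetric eigendecomposition); negative eigenvalues, which the
rescaled distances can produce, are reported but excluded from coordinates
and from the explained-variance denominator. Axis signs are fixed by
making each axis's largest-magnitude loading positive. The implementation
is cross-checked against scikit-bio's PCoA in the test suite.

## Temporal outlier scan

Per broodline, each locus's tracked-allele frequency is regressed on
generation index by OLS; a missing generation keeps its true spacing
(abscissa 0, 2, 3 for a line lacking generation 1), because slopes are
per-generation rates. Frequencies are not variance-stabilised: the scan is
defined on raw frequencies, and the Q–Q construction absorbs the overall
scale.

The m slopes are ranked, assigned Blom plotting positions
zᵢ = Φ⁻¹((i − 3/8)/(m + ¼)), and compared to a straight reference line.
Two decisions here were genuinely open:

- **Reference-line anchors.** The line passes through the paired
  5%/95%-quantile points of (theoretical, observed). Anchoring at the
  quartiles is the more common robust convention, but drift makes the slope
  distribution a scale mixture over p(1−p) with mildly heavy tails, and a
  quartile-anchored line underestimates the tail spread enough to flag
  ~3.8% of loci at nominal α = 0.01 under a pure-drift null — nearly four
  times nominal. The 5/95 anchors still give the extreme tail (the
  suspected outliers) essentially no leverage while tracking the mixture's
  spread; the null rate under the validation conditions is ~1.1%.
- **Standardisation of deviations.** With d = |b − e|, the statistic is
  X = d² / mean(d²), referred to χ² with 1 df. Standardising by the mean
  *squared* deviation makes X scale-invariant (the flagged set is unchanged
  by an affine transform of the slopes — a property the scan should have,
  since the frequency scale is arbitrary) and makes the deviation cutoff
  √(6.635) ≈ 2.58 RMS deviations, i.e. a data-dependent multiple of the
  *mean absolute* deviation: ≈3.23× when deviations are half-normal, larger
  for heavier tails (3.4–6.6× across the demo scans). Each scan reports its
  realized multiple. Flagging is two-sided in d; in practice flagged loci
  are tail loci whose slopes exceed the normal expectation.

Loci with fewer than two defined generations are excluded from the Q–Q fit
and reported as unscannable (distinct from not significant).

## FST–heterozygosity outlier scan

Year classes within one broodline are the "populations" of a multi-group
Weir–Cockerham (1984) θ; Hₑ = 2p̄(1−p̄) with p̄ the sample-size-weighted
mean frequency. Year classes with fewer than 8 fish are excluded from the
scan entirely (allele frequencies from N ≤ 7 fish produce spuriously high
θ).

The neutral null is **temporal drift**, not an island model: the groups
are generations of a single line, so the honest neutral model is
multi-generation Wright–Fisher drift sampled at the observed group sizes
with Hardy–Weinberg genotype draws. This is a deliberate departure from
island-model coalescent nulls used by classic FST-outlier software;
mutation is omitted (negligible over four generations at SNP scale).

Calibration mimics the "neutral mean FST first" idea: start from the mean
observed θ, bisect on the drift effective size until the simulated mean θ
(same estimator, same group structure, common random numbers) matches,
build a provisional envelope, drop observed loci outside it, and repeat to
convergence (≤ 10 iterations). One subtlety matters: a trimmed observed
mean must be matched against an **equally trimmed** simulated mean —
matching it to the untrimmed simulated mean biases the calibrated size
upward by ~35% and visibly distorts the null p-value distribution
(Kolmogorov–Smirnov distance ~0.05 instead of ~0.01 against uniform).

The final envelope uses 50,000 simulated loci with founder frequencies
Uniform(0.02, 0.98) (spanning the observed Hₑ range), ≥ 20 equal-count
Hₑ bins, per-bin FST quantiles at (1−ci)/2 and 1−(1−ci)/2 (ci = 0.95),
linearly interpolated between bin centers. Per-locus empirical p is the
plain fraction of bin-matched simulated loci with FST ≥ observed — it can
be exactly 0 for loci beyond every simulated value, which is what lets the
Benjamini–Hochberg step-up (FDR 0.1) reject at genome scale; an add-one
Monte-Carlo estimator would floor p above every BH threshold. Observed
Hₑ outside the simulated range falls back to the nearest bin with a
warning. Lower-tail (balancing-selection) flags are computed symmetrically
but reported separately and never fed to consensus, which is about
directional selection.

## Consensus, Venn accounting, gene annotation

The consensus matrix is locus × (method, broodline) with three states:
significant / tested-not-significant / not-tested. Tiers: candidate (≥ 1
significant test), highly significant (≥ 2 tests overall), per-broodline
consensus (≥ 2 of the 3 methods within a broodline). Venn region counts
(by method or by broodline) are exclusive and partition the flagged set.
Nearest-gene annotation takes, per retained mapped position of a candidate
tag, the k = 3 nearest genes within 100,000 bases, inclusive at the
boundary; distance is 0 inside a gene span, ties break by (distance, gene
start, gene id) for deterministic output. The window is measured from the
mapped tag start, not the SNP's offset within the ≤ 80-base tag — an
error bounded by the tag length, immaterial at a 100 kb window.

## Simulator

The generator reproduces the study conditions end to end: three broodlines,
four generations (one masked year class in broodline A, one N = 7 year
class in B), per-year sample sizes totalling 664, 5,392 loci with source
MAF ≥ 0.05, drift at Ne = 100 per generation, founder pools separated from
a common source by 3 drift generations (this produces the three-cluster
ordination), 50 loci under shared directional selection at s = 0.5
(gametic selection p′ = p(1+s)/(1+ps), mean |Δfreq| ≈ 0.2 over three
generations), and missingness rates drawn per sample from Beta(2, 38)
(mean 5%) and per locus from Beta(1, 39) (mean 2.5%), combined
independently. Generations are non-overlapping (no jack gene flow) by
default; optional migration and source-infusion fractions exist but
default to 0 since no quantitative admixture proportions are available.
Genotypes are Hardy–Weinberg draws within a generation (no inbreeding
parameter), so simulated truth loci pass the HWE filter by construction.

What the simulator does **not** emulate: linkage (loci are independent, so
no clustering of hits and no LD-induced dependence between tests),
genotyping error and allelic dropout beyond missingness, age-structured
demography and jacks, ascertainment bias of the SNP panel beyond the MAF
floor, and read-level artefacts. Passing validation therefore shows the
statistics behave correctly under drift + selection + sampling noise; it
does not certify behaviour under paralogy or strong LD.

## Validation problem sizes and expectations

The acceptance suite and `scripts/acceptance.py` use: 20 pure-drift
studies of 5,000 loci (3 broodlines × 4 generations × 50 fish) for type-I
error; one such study with a 50,000-simulation envelope for null p
uniformity and for envelope coverage (20,000 held-out loci); three studies
with 50 planted loci at s = 0.5 for power (detection = flagged in ≥ 1 of
the three broodline replicate scans, the design's replicate logic) and for
Fisher-exact enrichment of planted loci in the ≥ 2-test tier; 2,000-locus
studies for ordination recovery (k-means on two axes vs true labels;
negative control = founder year classes at zero founder divergence, where
the labels carry no signal); and 4,000 Wright–Fisher trajectories for the
drift-calibration identity E[(p_t − p₀)²] = p₀q₀(1 − (1 − 1/(2Ne))ᵗ).
These sizes keep the whole suite under a minute of simulation per
property while leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- The temporal scan's χ² reference is approximate: order-statistic
  deviations are heteroscedastic across ranks, so the realized null rate
  (~1%) tracks, but does not equal, the nominal α.
- The envelope's equal-count Hₑ binning assumes enough scannable loci
  (≥ 100 to calibrate; envelopes from < 1,000 simulations are refused).
- GenePop export encodes at most 99 alleles per locus (SNP data uses 2).
- With fewer than ~20 scannable loci the Q–Q fit is refused outright.
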