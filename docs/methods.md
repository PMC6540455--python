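# Methods

This note documents the statistical model behind `cptsig`, the
conventions and numerical choices that affect results, what the
synthetic generator does and does not emulate, and known limitations.

## Correlation kernel

All screens use the sample Pearson product-moment coefficient;
rank (Spearman) correlation is Pearson on mid-ranks (average ranks for
ties). Significance is the classical test of zero correlation:
t = r·√((n−2)/(1−r²)) referred to the central t distribution with n−2
degrees of freedom, always two-sided because every screen thresholds
|r|. For |r| = 1 the statistic diverges and the smallest representable
positive double is returned, keeping p in (0, 1].

The t-based p is exact under bivariate normality and a good
approximation otherwise; the test suite checks it against exhaustive
permutation enumeration at n ≤ 7, where the permutation p is granular
(multiples of 1/n!) and the two quantities agree to within a few
hundredths on average (bounds frozen from a 200-fixture pre-study of the
intrinsic gap between the two methods: mean |Δp| ≈ 0.02, worst ≈ 0.14
in the mid-range of p at n = 5).

**No multiple-testing correction is applied anywhere.** The screens use
raw thresholds; the expected false-positive count (feature count ×
p_max) is written to the log so the consequence is visible. At the
default thresholds (|r| ≥ 0.5, p < 0.01, n = 40) the |r| criterion
binds and the per-null-gene pass probability is ≈ 1.05 × 10⁻³.

## Signature pipeline conventions

* **Threshold edges**: |r| ≥ r_min is inclusive, p < p_max is strict.
* **Coherent driver-probe selection** is an exhaustive subset search
  (probe counts are single digits; refused above 15): maximize subset
  size subject to all pairwise r > r_pair_min, ties broken by larger
  mean pairwise r, then input order. Coherence is *signed* — a probe
  anti-correlated with its siblings is discarded — while the
  transcriptome screen uses |r|; the asymmetry is deliberate (an
  anti-correlated driver probe does not measure the driver, but a gene
  anti-correlated with the driver is biology).
* **Quantile convention**: quartiles (and hence the IQR used in
  standardization) use linear interpolation between order statistics
  ("type 7", the common software default). This choice moves probes
  that sit exactly on a screen boundary, which is why it is fixed
  rather than configurable.
* **Final reference**: genes are filtered against the driver's
  *aggregated* profile (mean of its retained standardized probes); a
  `per_probe` mode instead retains genes passing against any retained
  probe, reporting the best-|r| record. The aggregated mode is default
  because it uses the same per-gene currency on both sides of the
  correlation.
* **Driver exclusion**: the driver trivially correlates with itself at
  r = 1, so it is excluded from the signature count by default and its
  record always reported separately; a flag flips this.
* **Degenerate features**: zero-variance probes/genes are excluded per
  stage with logged counts, never errors, so large-cohort runs survive
  constant rows. All-degenerate inputs do error.
* The gene-level path correlates every gene against the driver's row on
  whatever scale the matrix carries (CPM for RNA-seq); it applies no
  transformation of its own.

## Clustering

Linkage is Ward's minimum-variance criterion with Euclidean distance
(via scipy's nearest-neighbor-chain implementation); heights follow the
convention sqrt(2·ΔESS), so two singletons merge at their Euclidean
distance, and are monotone non-decreasing. The test suite verifies the
full merge sequence (memberships and heights) against a naive
recompute-all-cluster-variances oracle. k-way partitions undo the last
k−1 merges; clusters are ranked by mean driver-reference value
(descending, ties by size then first leaf), giving the high / medium /
low naming at k = 3. "Log-ratio profiles" for heatmap correlation are
gene-wise median-centered log values (the log of the ratio to the
gene's median sample); a mean-centering alternative is available by
flag since the term admits both readings.

## Cumulative-proportion transform

Per sample: sort values descending, accumulate, and assign the gene at
position i the value 1 − cumsum(i)/total; ties all receive the value at
the *end* of their tie block, making the result deterministic and
order-free (a constant sample maps to all zeros). The transform is
monotone within a sample and exactly invariant to per-sample positive
scaling, which is the property that makes heterogeneous platforms
comparable. It is meaningful only on linear, non-negative intensities;
log-scale matrices are refused unless explicitly de-logged (2^x) by
flag — silent auto-detection is deliberately not offered. Datasets are
transformed separately, then intersected on shared symbols within
species, then paired through the ortholog map (strict one-to-one by
default, preventing double-counting in shared-gene counts).

## Synthetic-data generator

One latent driver factor per sample generates everything: the driver
gene's profile is the latent factor itself (loading adjustable;
settable to 0 for fully null datasets), module genes are
β·latent + σ·N(0,1), background genes are independent N(0,1). Probes
add independent N(0, probe_noise_sd) replicates per gene; the driver
receives 6 probes of which the last is replaced by independent noise to
exercise coherent-probe selection. The count-scale analog draws
negative-binomial counts with log-mean baseline + β·latent and fixed
dispersion 0.1, converted to CPM with per-sample totals. A monotone
platform distortion (per-sample power map value^γ times a random scale,
optional multiplicative log-normal jitter) exercises the
cross-platform stage.

Defaults are the verification conditions used throughout the tests:
40 samples, 120 module genes, 2000 background genes, 4 probes/gene,
β = 1, σ = 0.75 (population module correlation β/√(β²+σ²) = 0.8),
probe noise SD 0.25, NB baseline mean 200 counts. The 40-sample size
mirrors the human tumour cohort the method was developed on; β and σ
are chosen so the planted signal sits exactly at a strong-but-noisy
population r = 0.8.

Grouped cohorts for partition tests set the latent factor to per-group
levels (round-robin assignment) with optional within-group spread
(default 0); spacing adjacent group means 3σ/β apart separates each
module gene's group distributions by three gene-level noise SDs, under
which Ward at k = 3 recovers the partition essentially perfectly. With
substantial within-group latent spread the groups genuinely overlap and
no clustering method can recover them reliably — that regime is out of
scope for the recovery guarantee.

What the generator does *not* emulate: real Affymetrix intensity
distributions, batch structure, library-size biology, correlated
background modules (a single driver axis is assumed), or
platform-specific probe effects. Passing tests therefore demonstrate
correctness of the procedure and its calibration under the stated
model, not robustness to all failure modes of real accession data.

## Calibration checks

* Null calibration: background genes are independent of the driver
  reference, so their sample r follows the exact null law; observed
  pass fractions are required to fall inside central 99% binomial
  bounds of the analytic rate, both for aggregated exon-path nulls and
  for NB/CPM gene-level nulls (at NB mean 200 and dispersion 0.1 the
  normal-theory tail is accurate at n = 40).
* Power: at the defaults the aggregated module-gene correlation with
  the driver reference is ≈ β/√(β² + σ² + probe_noise²/probes) ≈ 0.79,
  giving per-gene sensitivity > 0.99 at the screen thresholds; mean
  planted-gene sensitivity ≥ 0.95 is asserted over 20 generator seeds.
* Small-sample behaviour: the effective |r| cutoff implied by p < p_max
  is t_crit/√(n−2+t_crit²); at n = 6, p < 0.05 this is 0.8114, so genes
  with 0.5 ≤ |r| < 0.811 are rejected — verified by construction of
  exact-correlation vectors.
* Cross-species: on cohorts where one species is a monotone distortion
  of the other, the between-species mean Spearman sits slightly above
  the within-species mean (matched sample pairs share ranks exactly up
  to jitter); the gap band [0.015, 0.030] was frozen from a
  100-replicate simulation of the same construction (mean ± 5 SD).

## Problem sizes

Tests and the acceptance script run on desk-scale instances chosen to
make every statistical assertion well-powered while keeping the whole
suite fast: 20 generator seeds for screen audits (40 samples × ~8.5k
probes each), 100 instances of ≤ 12 points for the Ward oracle, 10⁴
samples for generator calibration, and 800-gene cohorts for the
cross-species correlogram.

## Limitations

* The published pipeline counts on the original accession data (probe
  and gene counts of the human and murine cohorts) depend on the exact
  preprocessing of the deposited matrices, which is not fully
  specified at the source; this package reproduces the *procedure* and
  verifies it on synthetic ground truth, and will ingest the deposited
  matrices when supplied, but identical counts are not guaranteed.
* Pairwise-complete correlation is intentionally not offered: matrices
  with missing values are rejected at load so every reported n is
  unambiguous.
* No batch correction, probe-level normalization (e.g. RMA), or
  differential-expression testing; inputs are assumed already
  normalized, and DE belongs to dedicated tools.
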