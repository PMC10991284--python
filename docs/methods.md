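# Methods

This note documents the models, defaults and numerical choices behind
`gcbreg`, and what the synthetic benchmarks do and do not establish.

## Coordinate and data conventions

All intervals are 0-based half-open (BED). Peak strand is ignored:
accessibility and histone signal are unstranded. Count matrices are
feature × sample with unique feature ids; every sample carries a group
label, with one group designated the reference (WT).

## Interval engine

**Stitching** merges intervals connected by chains of gaps ≤ `max_gap`
(default 12,500 bp, the ROSE convention). Overlapping or bookended
intervals have gap 0. The operation is idempotent and every input index
is assigned to exactly one stitched region.

**GREAT basal-plus-extension domains** use the published defaults: basal
window 5 kb upstream / 1 kb downstream of the TSS (strand-oriented),
extension to the nearest neighboring basal-domain boundary on each side,
capped at 1 Mb and clipped at the chromosome start. When a neighbor's
basal domain intrudes into a gene's own basal window, the extension is
clamped back to the basal boundary — an extension never shrinks a basal
domain. Ambiguity in the source description was resolved in favor of
these defaults; the rule is pinned by an exhaustive-evaluation oracle in
the tests.

**TAD assignment** maps intervals to the TAD of maximal overlap (≥ 1 bp,
ties to the lexicographically first tad id) and genes by TSS containment
under the half-open convention. **Closest-TSS** distance is 0 for a TSS
inside the peak, otherwise the distance from the nearer peak edge; ties
resolve to the lexicographically smaller gene id. **Promoter** peaks are
those within ±5 kb of a TSS, boundary inclusive.

## Normalization and differential testing

Median-of-ratios size factors follow DESeq2: only features positive in
every sample enter; the factor is the per-sample median of
count/geometric-mean ratios. Promoter-read factors (for ChIP-style data
with global signal shifts) scale by total promoter counts, rescaled to
geometric mean 1.

The differential test is a deliberate simplification of the negative
binomial Wald machinery: log2FC of normalized group means with
pseudocount 0.5, Welch t on log2(normalized + 1), BH adjustment, calls
at padj < 0.01 and |FC| > 1.5. The contract is threshold logic plus
calibration, not DESeq2 bit-equality: on all-null NB data
(n = 5 vs 5, dispersion 0.05) the p < 0.05 rate sits near 0.046, and on
10% planted 4-fold effects the empirical FDR at padj < 0.01 stays below
0.02 with power above 0.9 (measured, not asserted by construction).
Zero-variance features receive p = 1. The known limitation: with fewer
than five replicates the Welch p-value has a floor (~5·10⁻⁵ at n = 4)
that can keep even large effects above a stringent BH threshold when the
feature count is small.

Cluster number selection uses the gap statistic with uniform reference
sets over the per-dimension bounding box (B = 100 by default), the
pairwise-distance form of W_k, and the 1-SE rule
Gap(k) ≥ Gap(k+1) − s_{k+1}; k-means uses k-means++ with 10 restarts,
tolerance 1e-6, seeded. Degenerate input (all rows identical) returns a
single cluster with a warning. Hierarchical clustering filters features
to the top variance fraction (default 10%) and exposes both Euclidean
and Manhattan distances under Ward linkage, since both appear in
published practice; Euclidean is the default.

## ROSE super-enhancers

Peaks whose center lies within 2,500 bp of any TSS are removed before
stitching (boundary inclusive). Stitched regions are ranked by the sum
of constituent peak signal, averaged across samples when a matrix is
given. The cutoff is the argmax of (scaled rank − scaled signal) on the
ascending sort — the tangent-slope-1 construction — with ties resolved
to the first maximum; regions strictly above the cutoff signal are
super. All-equal signals yield no cutoff and a warning. The super count
is invariant under uniform signal scaling, and the maximum-signal region
is always super when a cutoff exists.

Constituent summation assigns each count-matrix peak to the
maximal-overlap region (≥ 1 bp), so the assignment is a partition and
column sums of the SE matrix never exceed those of the peak matrix.
Differential SE activity divides summed counts by size factors computed
from the **full** peak matrix — normalizing by the regions under test
would absorb the effect being measured.

## Motif regression

The design is [intercept | motif indicators | GC fraction]; zero-variance
motif columns are dropped with a recorded reason, exact duplicates are
collapsed with an alias, and a residual rank deficiency is an error
naming the collinear set. Coefficients come from OLS; standard errors
from the HC1 sandwich (HC0–HC3 configurable). p-values are two-sided t
on the residual df, computed explicitly so the contract does not depend
on statsmodels' covariance-dependent default distribution. BH runs over
motif terms only — the intercept and GC are nuisance covariates, not
hypotheses. The remodeling score is the raw β in log2FC units. PWM
scanning (log-odds bits against a uniform background, both strands) is
provided as a convenience; the pipeline consumes precomputed motif
matrices.

## Enrichment statistics

Fisher's exact test reports the sample odds ratio ad/bc (∞, 0 or NaN on
zero cells) with the two-sided hypergeometric-enumeration p from scipy.
Preranked GSEA uses the weighted running sum (hit increments
|score|^w / Σ|score|^w with w = 1, miss decrements 1/(N − n_set)), ES at
the absolute extremum, a gene-label permutation null (the phenotype
permutation of the original procedure is not defined for preranked
input), per-sign NES normalization, permutation p with the +1
correction, and the standard NES-pool FDR. Ranking ties break by gene
id. The mutual-information pathway analysis computes
I(membership; group) in base-2 over the universe, a label-permutation p
(default nperm = 2000, here configurable), the 5–300 size filter and the
p < 0.005 threshold, and annotates significant pathways with per-group
hypergeometric over/under-representation. On null collections the
significant fraction stays below 5%, the randomization-FDR property the
procedure is used for.

## Trajectory model

The minimal fuzzifier is m(D, N) = 1 + (1418/N + 22.05)·D⁻² +
(12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134) — the published
Schwämmle–Jensen rule that suppresses spurious hard clusters on
structure-free data; it decreases with dimension and is always > 1.
Fuzzy c-means uses Bezdek's alternating updates (membership exponent
2/(m−1), centroid weights u^m), convergence when the maximum membership
change drops below 1e-6, best of 5 seeded restarts by objective; a point
coincident with a centroid takes membership 1 there (the limit
convention). Hard assignments for reporting use argmax membership with a
0.3 floor; genes below it stay unassigned. The default cluster count is
8, matching the published analysis, but is a plain parameter.

The per-cluster linear model pools gene × condition log2FC observations
and fits OLS on cell type + genotype + interaction with treatment coding
(references CB and C), classical t p-values. A single-gene cluster is
rejected: six observations cannot support six coefficients. The fit is
pooled rather than per-gene-aggregated; with one observation per gene
and condition there is no within-gene replication to support random
effects.

## Pseudotime procedures

Module scores bin genes into 24 equal-count bins by average expression
(rank-based so ties split evenly) and draw 5 control genes per signature
gene from its bin, excluding signature genes where possible, falling
back to with-replacement sampling (with a warning) only when a bin is
smaller than the control count. The score is mean signature minus mean
control expression per cell — invariant to adding a constant to all
genes.

The pseudotime shift test is Wilcoxon rank-sum: exact enumeration when
both groups have ≤ 8 observations and no ties, otherwise the
tie-corrected normal approximation with continuity correction; an
all-tied input returns p = 1.

The decile procedure rescales pseudotime to [0, 1], cuts pooled
quantile deciles, tests scores between genotypes per decile
(p = NA when a genotype is absent from a bin), adjusts by BH across the
testable deciles, and reports the difference of per-genotype cubic
smoothing splines at decile midpoints. The spline smoothing factor is
chosen from a small grid by generalized cross-validation with effective
df approximated from the knot count; duplicate pseudotime values are
averaged first, and fewer than four distinct values fall back to the
mean. A caveat the procedure inherits from its design: when genotypes
differ in pseudotime distribution, cells of the shifted genotype sit
systematically later *within* each decile, so within-decile tests can
reach significance even without genotype-specific expression — decile
significance localizes divergence but does not by itself separate
composition from modulation.

## Synthetic data generators

The generators emulate the processed forms of the study's assays at desk
scale and are pure functions of (config, seed).

* **Genome**: genes placed uniformly per chromosome (TSS + strand), TADs
  tiling each chromosome without overlap. Defaults: 2 chromosomes of
  2 Mb, 120 genes, 8 TADs each.
* **Peak counts**: 400 non-overlapping 500 bp peaks on a 1 kb lattice;
  counts negative binomial (shared dispersion 0.05, Poisson limit below
  1e-8) with mean base_mean · sf_s · 2^((Σ xβ + se)·g(s)), where motif
  presence x is Bernoulli(0.1) (recorded), β the planted effects
  (default motif_0 = −1), se the planted super-enhancer boost
  (log2 of 8 on three clusters of three adjacent peaks) and g(s) = 1 in
  non-reference samples. Planted SE clusters are placed TSS-distal
  (> 2.5 kb from any TSS), reflecting that super-enhancers are clusters
  of distal enhancers and that promoter-proximal peaks are excluded
  upstream of calling. Sample depth factors are Uniform(0.7, 1.4). Five
  replicates per genotype match the scale of the animal cohorts the
  procedures were designed for.
* **Cells**: pseudotime Beta-distributed per genotype, concentration 4,
  mean 0.5 + shift (defaults 0 / 0.05 / 0.1 / 0.2 for WT/C/K/CK; a shift
  pushing the mean outside (0, 1) is an error). 500 genes; the first 20
  are signature genes whose expression rises linearly with pseudotime
  (slope 1) over Gaussian noise (sd 0.5); CK signature expression drops
  by 0.5 past pseudotime 0.5, emulating a trajectory program that fails
  late in the double mutant. Expression is clipped at 0.
* **Clones**: symmetric Dirichlet frequencies with concentration
  α = 50·e/(1−e) for evenness e ∈ (0, 1] (e = 1 maps to exactly uniform
  frequencies, making the evenness → 1 clonality limit 1/√S exact),
  multinomial counts; zero-count clones are permitted and dropped by the
  diversity estimators.

What passing tests on these data show: the statistics recover planted
effects at the stated power and control their error rates under the
stated noise model. What they do not show: robustness to per-feature
dispersion heterogeneity, GC-dependent amplification bias, doublets or
ambient contamination in single-cell data, or clone-calling errors —
real-data features the generators deliberately omit.

## Clonality estimators

Hill numbers on observed frequencies: q = 1 is exp(−Σ p ln p), q ≠ 1 is
(Σ p^q)^(1/(1−q)); Productive Simpson Clonality is √(1/D) with D the
q = 2 Hill number, "productive" meaning zero-count clones are dropped
before frequencies are formed (productivity filtering itself is
upstream of this package). These are plug-in estimators — the asymptote
of coverage-based rarefaction estimates; no small-sample correction is
applied, so values on shallow repertoires are biased toward lower
diversity.

## Pipeline and provenance

`run_pipeline` executes simulate → differential → ROSE → SE differential
→ motif model → enrichment → trajectory → pseudotime → clonality,
writing each stage's TSV plus a JSON sidecar with parameters and SHA-256
hashes of stage inputs; `verify_manifest` flags stages whose recorded
input hashes no longer match. Reruns with the same config are
byte-identical. The global seed fans out to stage seeds through
`numpy.random.SeedSequence`.

## Benchmark problem sizes

The verification suite and the acceptance script use desk-scale problem
sizes chosen to give stable Monte-Carlo estimates: 1,000 random
instances for interval and cutoff oracles, 2,000 features for
differential calibration, 100 seeds × (500 peaks × 20 motifs) for motif
recovery, 20 seeds × 600 cells for decile localization, 10 generator
seeds for ROSE recovery. At these sizes the full suite runs in about
half a minute on one CPU.
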