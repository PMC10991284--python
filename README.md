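# gcbreg

Regulatory-genomics analyses for germinal-center (GC) B-cell enhancer
remodeling studies. The package reimplements, as a tested and reusable
pipeline, the computational procedures used to dissect how combined
haploinsufficiency of two chromatin modifiers (the CREBBP acetyltransferase
and the KMT2D methyltransferase; genotypes C, K and their combination CK
against wild type) rewires enhancer accessibility, transcriptional
trajectories, and B-cell-receptor clonality in follicular lymphoma models.

It is aimed at computational biologists who want the individual statistical
procedures — super-enhancer calling, differential accessibility, motif-effect
regression, enrichment statistics, pseudotime decile testing, repertoire
diversity — as importable, unit-tested functions, exercised end to end on
synthetic data with planted ground truth rather than on multi-hundred-GB
sequencing archives.

## What is implemented

**Super-enhancers (ROSE).** Peaks whose center lies within 2,500 bp of a TSS
are excluded, the rest are stitched at a 12,500 bp gap, and stitched regions
are ranked by total signal. With signals sorted ascending and both rank and
signal scaled to [0, 1], the cutoff sits at

&nbsp;&nbsp;&nbsp;&nbsp;i\* = argmax_i (scaled_rank_i − scaled_signal_i),

the point where the tangent to the ranked curve reaches slope 1; regions
with signal above the cutoff are super-enhancers. Differential
super-enhancer activity sums constituent peak counts (≥ 1 bp overlap,
maximal-overlap assignment) per region and normalizes with **genome-wide**
size factors from the full peak matrix.

**Differential features.** DESeq2-style median-of-ratios size factors
(factor_s = median over features of count_fs / geometric-mean_f), a Welch
t test on log2(normalized + 1), Benjamini–Hochberg adjustment, and calls at
padj < 0.01 and |FC| > 1.5. K-means cluster number is selected by the gap
statistic with the 1-SE rule; hierarchical clustering runs on the top 10%
most variable features.

**Motif model.** Per-peak accessibility log2FC is regressed on motif
presence and GC content,

&nbsp;&nbsp;&nbsp;&nbsp;log2FC ~ β₀ + x₁β₁ + … + xₙβₙ + GC·β_GC,

by OLS with heteroskedasticity-consistent (HC1) sandwich standard errors;
each βₘ is that TF's accessibility remodeling score, BH-adjusted across
motif terms.

**Enrichment.** Fisher exact odds ratios, hypergeometric
over-representation, preranked GSEA (weighted running sum, gene-label
permutation null, signed NES, NES-based FDR), and an information-theoretic
pathway analysis scoring I(pathway membership; gene group) in bits with a
permutation p-value, size filter 5–300 and significance threshold p < 0.005.

**Trajectory.** Fuzzy c-means clustering of per-gene log2FC profiles with
the Schwämmle–Jensen minimal fuzzifier
m(D, N) = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134),
and a pooled OLS of cluster log2FC on cell type (CB/CC) × genotype with
interaction, treatment-coded.

**Pseudotime.** Seurat-style module scores (expression-bin-matched control
genes, control value 5), Wilcoxon rank-sum pseudotime shift tests, and the
10-decile procedure: pooled-quantile deciles, per-decile Wilcoxon with BH,
and the difference of per-genotype smoothing splines at decile midpoints.

**Clonality.** Hill diversities (q = 1 exponential Shannon, q = 2 inverse
Simpson D) and Productive Simpson Clonality √(1/D) on clone abundance
tables, plus clonal fraction curves.

**Synthetic data.** Every input above can be generated with planted ground
truth: negative-binomial peak counts with motif-driven log2FC effects and
clustered high-signal super-enhancer regions, Beta-distributed pseudotime
with genotype shifts and a late-trajectory signature suppression, and
Dirichlet-multinomial clone tables of controlled evenness.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about ten seconds in total):

```bash
python analysis/01_simulate.py
python analysis/02_differential_peaks.py
python analysis/03_superenhancers.py
python analysis/04_motif_model.py
python analysis/05_enrichment.py
python analysis/06_trajectory.py
python analysis/07_pseudotime.py
python analysis/08_clonality.py
```

Selected output, with the planted truth in parentheses:

```
CK vs WT: 9 peaks gained, 7 peaks lost (of 400; padj<0.01, |FC|>1.5)
28 super-enhancers among 114 stitched regions (cutoff signal 418.1)
motif_0: planted beta -1.00, estimated -1.088 (robust SE 0.039, padj 4.82e-94)
differential call x SE membership: OR = 4.0, Fisher p = 1.82e-02
GSEA motif_0: ES -1.00, NES -2.54, p 0.004 (planted repressive motif ranks low)
pseudotime shift WT vs CK: U = 43590, p = 7.91e-29
7 of 10 deciles significant; delta range [-0.530, +0.205]
clonality ordering: WT < C < K < CK
```

The gained peaks are the planted super-enhancer clusters (8× signal in
mutants), the lost peaks carry the planted repressive motif (β = −1, i.e. a
2-fold accessibility drop), the motif regression pins that coefficient with
a tight robust SE while the eleven null motifs stay flat, the decile
procedure localizes the planted late-trajectory signature suppression
(−0.5 past pseudotime 0.5), and the clone tables reproduce the planted
evenness gradient as rising Simpson clonality.

The same stages are exposed as a CLI (`gcbreg simulate|diffacc|rose|
se-diff|motif-model|gsea|page|fisher|trajectory|module-score|delta-spline|
clonality|run-all`); `gcbreg run-all --seed 1 --outdir out/` runs everything
with a provenance manifest (per-stage JSON sidecars with parameter and
SHA-256 input hashes; reruns are byte-identical).

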