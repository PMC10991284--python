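"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, with the
planted effects recorded in a :class:`SyntheticTruth`, so downstream
stages are testable end to end without external downloads.  The
generators emulate the processed forms of the study's assays:

* a genome of genes (TSS + strand) and non-overlapping TADs tiling
  each chromosome;
* a peak x sample accessibility count matrix with negative-binomial
  noise, motif-driven log2FC effects in non-reference groups, and
  clustered high-signal super-enhancer regions;
* a cell table with genotype-shifted Beta pseudotime and signature
  expression increasing along pseudotime;
* clone abundance vectors of controlled evenness (symmetric Dirichlet
  frequencies, multinomial counts).

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, GenomicInterval

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "Genome",
    "gen_genome",
    "gen_peak_counts",
    "gen_cells",
    "gen_clones",
]


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults describe a desk-scale version of the study design: four
    genotypes (WT reference plus the three mutants C, K, CK), a few
    replicates per genotype, negative-binomial accessibility counts,
    and a handful of planted motif and super-enhancer effects.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_peaks: int = 400
    n_samples_per_group: int = 5
    groups: tuple = ("WT", "C", "K", "CK")
    reference_group: str = "WT"
    n_genes: int = 120
    n_tads_per_chrom: int = 8
    n_motifs: int = 12
    motif_prob: float = 0.1
    planted_motif_effects: dict = field(default_factory=lambda: {"motif_0": -1.0})
    n_se_clusters: int = 3
    se_cluster_size: int = 3
    se_peak_multiplier: float = 8.0
    # planted clusters are kept TSS-distal: super-enhancers are clusters of
    # distal enhancers, and promoter-proximal peaks are excluded upstream
    se_tss_clearance: int = 2_500
    nb_dispersion: float = 0.05
    base_mean: float = 100.0
    n_cells_per_group: int = 400
    pseudotime_shift: dict = field(
        default_factory=lambda: {"WT": 0.0, "C": 0.05, "K": 0.1, "CK": 0.2}
    )
    signature_effect: float = 1.0
    n_signature_genes: int = 20
    # genotype-specific signature modulation: additive shift on signature
    # genes for cells past the onset pseudotime, emulating a trajectory
    # program that fails late in mutant cells
    signature_late_suppression: dict = field(default_factory=lambda: {"CK": -0.5})
    suppression_onset: float = 0.5
    n_clones: int = 50
    clone_evenness: float = 0.5
    clone_total_reads: int = 10_000

    def validate(self) -> None:
        positive = {
            "n_chroms": self.n_chroms,
            "chrom_length": self.chrom_length,
            "n_peaks": self.n_peaks,
            "n_samples_per_group": self.n_samples_per_group,
            "n_genes": self.n_genes,
            "n_tads_per_chrom": self.n_tads_per_chrom,
            "n_motifs": self.n_motifs,
            "base_mean": self.base_mean,
            "n_clones": self.n_clones,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.se_peak_multiplier <= 0:
            raise ValueError("se_peak_multiplier must be > 0")
        if not (0 < self.clone_evenness <= 1):
            raise ValueError("clone_evenness must lie in (0, 1]")
        if self.reference_group not in self.groups:
            raise ValueError("groups must contain the reference group")
        # peaks are 500 bp wide and non-overlapping within a chromosome
        per_chrom = -(-self.n_peaks // self.n_chroms)
        if per_chrom * 1000 > self.chrom_length:
            raise ValueError(
                "chrom_length too small to host n_peaks non-overlapping peaks"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    peak_log2fc: Optional[pd.DataFrame] = None  # peaks x non-reference groups
    motif_effects: dict = field(default_factory=dict)
    se_regions: list = field(default_factory=list)  # lists of peak ids per cluster
    gene_differential: dict = field(default_factory=dict)
    pseudotime_params: dict = field(default_factory=dict)
    clone_frequencies: Optional[np.ndarray] = None


@dataclass
class Genome:
    genes: list  # GeneAnnotation
    tads: dict  # tad_id -> GenomicInterval
    chrom_lengths: dict


def gen_genome(cfg: SimConfig) -> Genome:
    """Genes placed uniformly; TADs tile each chromosome without overlap."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genes: list[GeneAnnotation] = []
    per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    gid = 0
    for chrom in chroms:
        n_here = min(per_chrom, cfg.n_genes - gid)
        tss = np.sort(rng.integers(0, cfg.chrom_length, size=n_here))
        strands = rng.choice(["+", "-"], size=n_here)
        for t, s in zip(tss, strands):
            genes.append(GeneAnnotation(f"gene_{gid:04d}", chrom, int(t), str(s)))
            gid += 1
    tads: dict[str, GenomicInterval] = {}
    tid = 0
    for chrom in chroms:
        bounds = np.linspace(0, cfg.chrom_length, cfg.n_tads_per_chrom + 1).astype(int)
        for a, b in zip(bounds[:-1], bounds[1:]):
            tads[f"tad_{tid:03d}"] = GenomicInterval(chrom, int(a), int(b))
            tid += 1
    return Genome(genes=genes, tads=tads, chrom_lengths={c: cfg.chrom_length for c in chroms})


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with Var = mu + dispersion * mu^2; Poisson limit at tiny dispersion."""
    if dispersion < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def gen_peak_counts(cfg: SimConfig, genome: Genome):
    """Peak count matrix with planted motif and super-enhancer effects.

    Counts for peak p, sample s are negative binomial with mean
    ``base_mean * sf_s * 2**((sum_m x_pm beta_m + se_p) * g(s))`` where
    x_pm is Bernoulli(motif_prob) motif presence, beta_m the planted
    motif effect, se_p the planted super-enhancer multiplier effect
    (log2 of ``se_peak_multiplier`` on clustered peaks), and g(s)=1 for
    non-reference samples.  Returns (counts DataFrame, sample groups,
    peak intervals, motif matrix, gc vector, truth).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom = -(-cfg.n_peaks // cfg.n_chroms)

    peak_width = 500
    peaks: list[GenomicInterval] = []
    for chrom in chroms:
        n_here = min(per_chrom, cfg.n_peaks - len(peaks))
        # non-overlapping placement on a 1 kb lattice, then jitter within slot
        slots = rng.choice(cfg.chrom_length // 1000, size=n_here, replace=False)
        for s in np.sort(slots):
            start = int(s) * 1000 + int(rng.integers(0, 1000 - peak_width))
            peaks.append(GenomicInterval(chrom, start, start + peak_width))
    peak_ids = [f"peak_{i:05d}" for i in range(len(peaks))]

    motif_ids = [f"motif_{m}" for m in range(cfg.n_motifs)]
    for m in cfg.planted_motif_effects:
        if m not in motif_ids:
            raise ValueError(f"planted motif {m} not among generated motifs")
    X = rng.binomial(1, cfg.motif_prob, size=(len(peaks), cfg.n_motifs))
    motifs = pd.DataFrame(X, index=peak_ids, columns=motif_ids)
    gc = pd.Series(rng.uniform(0.2, 0.8, size=len(peaks)), index=peak_ids, name="gc")

    beta = np.array([cfg.planted_motif_effects.get(m, 0.0) for m in motif_ids])
    motif_lfc = X @ beta

    # super-enhancer clusters: runs of adjacent peaks with boosted signal
    se_effect = np.zeros(len(peaks))
    se_regions: list[list[str]] = []
    if cfg.n_se_clusters > 0:
        tss_by_chrom: dict[str, np.ndarray] = {}
        for g in genome.genes:
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        tss_by_chrom = {c: np.asarray(v, float) for c, v in tss_by_chrom.items()}

        def distal(i: int) -> bool:
            tss = tss_by_chrom.get(peaks[i].chrom)
            if tss is None or tss.size == 0:
                return True
            return float(np.min(np.abs(tss - peaks[i].center))) > cfg.se_tss_clearance

        eligible = [
            a
            for a in range(len(peaks) - cfg.se_cluster_size + 1)
            if all(
                peaks[a + j].chrom == peaks[a].chrom and distal(a + j)
                for j in range(cfg.se_cluster_size)
            )
        ]
        if len(eligible) < cfg.n_se_clusters:
            raise ValueError("not enough TSS-distal peak runs for SE clusters")
        anchors = rng.choice(eligible, size=cfg.n_se_clusters, replace=False)
        for a in np.sort(anchors):
            ids = []
            for j in range(cfg.se_cluster_size):
                se_effect[a + j] += np.log2(cfg.se_peak_multiplier)
                ids.append(peak_ids[a + j])
            se_regions.append(ids)

    samples = []
    groups: dict[str, str] = {}
    for g in cfg.groups:
        for r in range(cfg.n_samples_per_group):
            sid = f"{g}_{r + 1}"
            samples.append(sid)
            groups[sid] = g
    sf = rng.uniform(0.7, 1.4, size=len(samples))

    lfc = motif_lfc + se_effect
    counts = np.empty((len(peaks), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        is_mut = groups[sid] != cfg.reference_group
        mu = cfg.base_mean * sf[j] * 2.0 ** (lfc if is_mut else 0.0)
        counts[:, j] = _nb_draw(rng, mu, cfg.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=peak_ids, columns=samples)

    non_ref = [g for g in cfg.groups if g != cfg.reference_group]
    truth = SyntheticTruth(
        peak_log2fc=pd.DataFrame(
            {g: lfc for g in non_ref}, index=peak_ids
        ),
        motif_effects={m: cfg.planted_motif_effects.get(m, 0.0) for m in motif_ids},
        se_regions=se_regions,
    )
    return counts_df, groups, peaks, motifs, gc, truth


def gen_cells(cfg: SimConfig, genome: Optional[Genome] = None):
    """Cell table with genotype-shifted pseudotime and signature genes.

    Pseudotime is Beta-distributed per genotype with mean 0.5 shifted
    by ``pseudotime_shift[genotype]`` at fixed concentration 4; the
    first ``n_signature_genes`` genes gain expression linearly along
    pseudotime with slope ``signature_effect`` plus unit-free Gaussian
    noise (sd 0.5).  ``signature_late_suppression`` adds a
    genotype-specific shift to signature genes in cells past
    ``suppression_onset``, emulating a trajectory program that diverges
    late in mutants.  Returns (CellTable, signature gene list, truth).
    """
    from .pseudotime import CellTable

    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    nu = 4.0
    params = {}
    for g in cfg.groups:
        mu = 0.5 + cfg.pseudotime_shift.get(g, 0.0)
        if not (0 < mu < 1):
            raise ValueError(
                f"pseudotime_shift for {g} pushes the Beta mean outside (0, 1)"
            )
        params[g] = (mu * nu, (1 - mu) * nu)

    n_genes = max(cfg.n_signature_genes * 25, 500)
    gene_ids = [f"sgene_{i:04d}" for i in range(n_genes)]
    signature = gene_ids[: cfg.n_signature_genes]

    rows, pt_all, geno_all = [], [], []
    cell_ids = []
    for g in cfg.groups:
        a, b = params[g]
        pt = rng.beta(a, b, size=cfg.n_cells_per_group)
        for i, t in enumerate(pt):
            cell_ids.append(f"{g}_cell_{i:04d}")
            pt_all.append(t)
            geno_all.append(g)
    pt_arr = np.asarray(pt_all)
    base = rng.normal(1.0, 0.2, size=n_genes).clip(min=0.1)
    expr = rng.normal(0.0, 0.5, size=(len(cell_ids), n_genes)) + base
    expr[:, : cfg.n_signature_genes] += cfg.signature_effect * pt_arr[:, None]
    geno_arr = np.asarray(geno_all)
    for g, shift in cfg.signature_late_suppression.items():
        late = (geno_arr == g) & (pt_arr > cfg.suppression_onset)
        expr[np.ix_(late, np.arange(cfg.n_signature_genes))] += shift
    expr = np.maximum(expr, 0.0)

    cells = pd.DataFrame(
        {"genotype": geno_all, "pseudotime": pt_arr},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    expression = pd.DataFrame(expr, index=cells.index, columns=gene_ids)
    truth = SyntheticTruth(pseudotime_params={g: params[g] for g in cfg.groups})
    return CellTable(cells, expression), signature, truth


def gen_clones(
    n_clones: int,
    clone_evenness: float,
    total_reads: int,
    seed: int = 0,
) -> tuple[pd.Series, SyntheticTruth]:
    """Clone abundance counts of controlled evenness.

    Frequencies come from a symmetric Dirichlet whose concentration
    grows with ``clone_evenness`` (alpha = 50 e / (1 - e)); evenness 1
    yields exactly uniform frequencies.  Counts are multinomial with
    ``total_reads`` draws; zero-count clones are permitted and dropped
    downstream.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not (0 < clone_evenness <= 1):
        raise ValueError("clone_evenness must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if clone_evenness == 1.0 or n_clones == 1:
        freqs = np.full(n_clones, 1.0 / n_clones)
    else:
        alpha = 50.0 * clone_evenness / (1.0 - clone_evenness)
        freqs = rng.dirichlet(np.full(n_clones, alpha))
    counts = rng.multinomial(total_reads, freqs)
    ser = pd.Series(
        counts, index=[f"clone_{i:04d}" for i in range(n_clones)], name="count"
    )
    return ser, SyntheticTruth(clone_frequencies=freqs)
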