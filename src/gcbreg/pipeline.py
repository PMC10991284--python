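"""End-to-end pipeline orchestration with a provenance manifest.

``run_pipeline`` executes the stages in dependency order on a synthetic
dataset — simulate, normalize, differential peaks, ROSE, differential
super-enhancers, motif model, enrichment, trajectory, pseudotime
deciles, clonality — writing each stage's table plus a JSON sidecar
recording parameters, the seed, and SHA-256 hashes of the stage inputs.
Reruns with the same config are byte-identical, and the manifest's
hash chain makes stale or corrupted intermediates detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .differential import PeakCountMatrix, diff_test, size_factors, vst_like
from .enrichment import GeneSetCollection, gsea_preranked
from .intervals import annotate_feature
from .motifs import build_design, fit_remodeling_model
from .pseudotime import decile_delta, module_score, pseudotime_shift_test
from .simulate import SimConfig, gen_cells, gen_clones, gen_genome, gen_peak_counts
from .superenhancer import (
    link_se_to_genes,
    rose_call,
    se_differential,
    se_sum_constituents,
)
from .trajectory import fuzzy_cmeans, hard_assignments, select_fuzzifier

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_stage(outdir: Path, name: str, df: pd.DataFrame, params: dict, inputs: list[Path]) -> Path:
    path = outdir / f"{name}.tsv"
    df.to_csv(path, sep="\t")
    sidecar = {
        "stage": name,
        "params": params,
        "inputs": {str(p.name): _sha256(p) for p in inputs},
        "output_sha256": _sha256(path),
    }
    (outdir / f"{name}.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def verify_manifest(outdir: Path) -> list[str]:
    """Return the names of stages whose recorded input hashes are stale."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    stale = []
    for stage in manifest["stages"]:
        sidecar = json.loads((outdir / f"{stage}.json").read_text())
        for fname, digest in sidecar["inputs"].items():
            if _sha256(outdir / fname) != digest:
                stale.append(stage)
                break
    return stale


def run_pipeline(cfg: SimConfig, outdir) -> dict:
    """Run every stage on synthetic data; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    # --- simulate -------------------------------------------------------
    genome = gen_genome(cfg)
    counts, groups, peaks, motifs, gc, truth = gen_peak_counts(cfg, genome)
    peak_ids = list(counts.index)
    gio.write_bed(outdir / "peaks.bed", peaks, names=peak_ids)
    gio.write_genes_tsv(outdir / "genes.tsv", genome.genes)
    gio.write_tads_bed(outdir / "tads.bed", genome.tads)
    gio.write_counts_tsv(outdir / "peak_counts.tsv", counts)
    motifs.to_csv(outdir / "motifs.tsv", sep="\t")
    gc.to_frame().to_csv(outdir / "gc.tsv", sep="\t")
    truth_obj = {
        "motif_effects": truth.motif_effects,
        "se_regions": truth.se_regions,
    }
    gio.write_json(outdir / "truth.json", truth_obj)
    sim_inputs = [outdir / "peaks.bed", outdir / "peak_counts.tsv"]
    stages.append("simulate")
    (outdir / "simulate.json").write_text(json.dumps({
        "stage": "simulate", "params": asdict(cfg),
        "inputs": {},
        "output_sha256": _sha256(outdir / "peak_counts.tsv"),
    }, indent=2, sort_keys=True, default=str) + "\n")

    # --- differential accessibility ------------------------------------
    pcm = PeakCountMatrix(counts, groups, intervals=peaks)
    sf = size_factors(counts)
    test_group = [g for g in cfg.groups if g != cfg.reference_group][-1]
    diff = diff_test(pcm, cfg.reference_group, test_group, factors=sf)
    _write_stage(outdir, "differential_peaks", diff,
                 {"reference": cfg.reference_group, "test": test_group,
                  "padj": 0.01, "fc": 1.5},
                 [outdir / "peak_counts.tsv"])
    stages.append("differential_peaks")

    # --- ROSE + differential super-enhancers ----------------------------
    norm = counts / sf
    signal = norm.values
    se = rose_call(peaks, signal, genome.genes)
    se_out = se.copy()
    se_out["members"] = se_out["members"].map(
        lambda ms: ",".join(peak_ids[m] for m in ms)
    )
    _write_stage(outdir, "superenhancers", se_out,
                 {"stitch_gap": 12500, "tss_exclusion": 2500},
                 [outdir / "peak_counts.tsv", outdir / "genes.tsv"])
    stages.append("superenhancers")

    se_counts = se_sum_constituents(se, peaks, counts)
    se_diff = se_differential(se_counts, sf, groups, cfg.reference_group)
    links = link_se_to_genes(se, genome.tads, genome.genes)
    se_diff["linked_genes"] = [
        ",".join(g for g, _ in links.get(se_id, [])) for se_id in se_diff.index
    ]
    _write_stage(outdir, "se_differential", se_diff,
                 {"reference": cfg.reference_group},
                 [outdir / "superenhancers.tsv"])
    stages.append("se_differential")

    # --- motif model ----------------------------------------------------
    design = build_design(motifs, gc.values)
    effects = fit_remodeling_model(diff["log2FC"].values, design)
    _write_stage(outdir, "motif_effects", effects,
                 {"cov_type": "HC1"},
                 [outdir / "motifs.tsv", outdir / "gc.tsv",
                  outdir / "differential_peaks.tsv"])
    stages.append("motif_effects")

    # --- enrichment: GSEA of the planted motif's peak targets -----------
    planted = [m for m, b in truth.motif_effects.items() if b != 0]
    ranked = pd.Series(diff["log2FC"].values, index=counts.index)
    gene_sets = {}
    for m in planted:
        members = set(counts.index[motifs[m].values.astype(bool)])
        if 0 < len(members) < len(ranked):
            gene_sets[f"peaks_with_{m}"] = members
    if gene_sets:
        gsea = gsea_preranked(ranked, gene_sets, nperm=200, seed=cfg.seed)
        _write_stage(outdir, "gsea_motif_targets", gsea,
                     {"nperm": 200}, [outdir / "differential_peaks.tsv"])
        stages.append("gsea_motif_targets")

    # --- trajectory clustering on per-peak profiles ---------------------
    vst = vst_like(counts, sf)
    prof = pd.DataFrame({
        g: vst[pcm.samples_in(g)].mean(axis=1)
        - vst[pcm.samples_in(cfg.reference_group)].mean(axis=1)
        for g in cfg.groups if g != cfg.reference_group
    })
    m = select_fuzzifier(prof.shape[0], prof.shape[1])
    fc = fuzzy_cmeans(prof.values, c=min(4, prof.shape[0]), m=m, seed=cfg.seed)
    traj = pd.DataFrame(
        fc.membership, index=prof.index,
        columns=[f"cluster_{i}" for i in range(fc.membership.shape[1])],
    )
    traj["hard"] = hard_assignments(fc)
    _write_stage(outdir, "trajectory_clusters", traj,
                 {"fuzzifier": m}, [outdir / "peak_counts.tsv"])
    stages.append("trajectory_clusters")

    # --- pseudotime -----------------------------------------------------
    cells, signature, _ = gen_cells(cfg, genome)
    scores = module_score(cells.expression, signature, seed=cfg.seed)
    mut = [g for g in cfg.groups if g != cfg.reference_group][-1]
    w, p_shift = pseudotime_shift_test(cells, cfg.reference_group, mut)
    deciles = decile_delta(cells, scores, cfg.reference_group, mut)
    deciles.attrs["pseudotime_shift_p"] = p_shift
    cells.cells.assign(module_score=scores).to_csv(outdir / "cells.tsv", sep="\t")
    _write_stage(outdir, "decile_delta", deciles,
                 {"reference": cfg.reference_group, "test": mut,
                  "pseudotime_shift_W": w, "pseudotime_shift_p": p_shift},
                 [outdir / "cells.tsv"])
    stages.append("decile_delta")

    # --- clonality ------------------------------------------------------
    clone_rows = {}
    for g in cfg.groups:
        evenness = max(0.05, cfg.clone_evenness - 0.1 * list(cfg.groups).index(g) / len(cfg.groups))
        clones, _ = gen_clones(cfg.n_clones, evenness, cfg.clone_total_reads,
                               seed=cfg.seed + list(cfg.groups).index(g))
        from .clonality import diversity_summary

        clone_rows[g] = diversity_summary(clones.values)
    clon = pd.DataFrame(clone_rows).T
    _write_stage(outdir, "clonality", clon, {"n_clones": cfg.n_clones}, [])
    stages.append("clonality")

    manifest = {
        "seed": cfg.seed,
        "stages": stages,
        "outputs": {
            f"{s}.tsv": _sha256(outdir / f"{s}.tsv") for s in stages
            if (outdir / f"{s}.tsv").exists()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
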