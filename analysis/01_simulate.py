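"""Generate the synthetic study dataset.

Emits a four-genotype (WT/C/K/CK) accessibility count matrix with a
planted closing motif effect (beta = -1 on motif_0) and three planted
super-enhancer clusters, plus gene/TAD annotations, a cell table with
genotype-shifted pseudotime, and clone abundance tables — everything
the downstream steps consume, with the planted truth in truth.json.

Run from the repository root: python analysis/01_simulate.py
"""

from pathlib import Path

from gcbreg import io as gio
from gcbreg.simulate import SimConfig, gen_cells, gen_clones, gen_genome, gen_peak_counts

OUT = Path("results/data")
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    genome = gen_genome(cfg)
    counts, groups, peaks, motifs, gc, truth = gen_peak_counts(cfg, genome)

    gio.write_bed(OUT / "peaks.bed", peaks, names=list(counts.index))
    gio.write_genes_tsv(OUT / "genes.tsv", genome.genes)
    gio.write_tads_bed(OUT / "tads.bed", genome.tads)
    gio.write_counts_tsv(OUT / "peak_counts.tsv", counts)
    motifs.to_csv(OUT / "motifs.tsv", sep="\t")
    gc.to_frame().to_csv(OUT / "gc.tsv", sep="\t")
    import pandas as pd

    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}).to_csv(
        OUT / "samples.tsv", sep="\t", index=False
    )
    gio.write_json(OUT / "truth.json", {
        "seed": cfg.seed,
        "motif_effects": truth.motif_effects,
        "se_regions": truth.se_regions,
    })

    cells, signature, _ = gen_cells(cfg, genome)
    cells.cells.to_csv(OUT / "cells.tsv", sep="\t")
    cells.expression.to_csv(OUT / "cell_expression.tsv", sep="\t")
    (OUT / "signature_genes.txt").write_text("\n".join(signature) + "\n")

    for i, g in enumerate(cfg.groups):
        evenness = {"WT": 0.8, "C": 0.5, "K": 0.4, "CK": 0.15}.get(g, 0.5)
        clones, _ = gen_clones(cfg.n_clones, evenness, cfg.clone_total_reads,
                               seed=cfg.seed + i)
        clones.to_frame().to_csv(OUT / f"clones_{g}.tsv", sep="\t")

    print(f"simulated {counts.shape[0]} peaks x {counts.shape[1]} samples, "
          f"{len(genome.genes)} genes, {len(genome.tads)} TADs -> {OUT}")
    print(f"planted: motif_0 beta=-1, {len(truth.se_regions)} SE clusters, "
          f"clone evenness gradient WT > C > K > CK")


if __name__ == "__main__":
    main()
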