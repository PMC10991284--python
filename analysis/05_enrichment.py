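"""Enrichment statistics on the differential peaks.

Three readouts mirroring the study's association analyses:
(1) Fisher odds ratio associating the differential-peak call with
    super-enhancer constituent membership (feature association),
(2) preranked GSEA of motif-bearing peak sets against the log2FC
    ranking (the planted closing motif should enrich at the bottom),
(3) mutual-information pathway analysis of the call labels against
    the same peak sets.

Run after 03_superenhancers.py and 04_motif_model.py.
"""

import json
from pathlib import Path

import pandas as pd

from gcbreg import io as gio
from gcbreg.enrichment import (
    GeneSetCollection,
    fisher_exact_or,
    gsea_preranked,
    page_mi,
)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    diff = pd.read_csv(OUT / "differential_peaks_CK_vs_WT.tsv", sep="\t", index_col=0)
    motifs = gio.read_counts_tsv(DATA / "motifs.tsv").loc[diff.index]
    se = pd.read_csv(OUT / "superenhancers.tsv", sep="\t", index_col=0)
    truth = json.loads((DATA / "truth.json").read_text())
    planted_motifs = [m for m, b in truth["motif_effects"].items() if float(b) != 0]

    # Fisher: differential call x super-enhancer constituency
    constituents = set()
    for ms in se.loc[se["is_super"], "members"]:
        constituents |= set(str(ms).split(","))
    in_se = diff.index.isin(constituents)
    called = diff["call"].values != "ns"
    a = int((called & in_se).sum())
    b = int((called & ~in_se).sum())
    c = int((~called & in_se).sum())
    d = int((~called & ~in_se).sum())
    odds, p = fisher_exact_or([[a, b], [c, d]])
    pd.DataFrame(
        {"a_called_in_se": [a], "b_called_out": [b], "c_ns_in_se": [c],
         "d_ns_out": [d], "odds_ratio": [odds], "p": [p]}
    ).to_csv(OUT / "fisher_call_by_se.tsv", sep="\t", index=False)
    print(f"differential call x SE membership: OR = {odds:.1f}, Fisher p = {p:.2e}")

    # GSEA: peaks bearing each motif against the log2FC ranking
    sets = {
        m: set(motifs.index[motifs[m].astype(bool)])
        for m in motifs.columns
        if 0 < motifs[m].sum() < len(motifs)
    }
    gsea = gsea_preranked(diff["log2FC"], sets, nperm=500, seed=1)
    gsea.to_csv(OUT / "gsea_motif_sets.tsv", sep="\t")
    for m in planted_motifs:
        print(f"GSEA {m}: ES {gsea.loc[m, 'es']:+.2f}, NES {gsea.loc[m, 'nes']:+.2f}, "
              f"p {gsea.loc[m, 'p']:.3f} (planted repressive motif ranks low)")

    # MI pathway analysis of the call labels over motif sets
    labels = dict(zip(diff.index, diff["call"]))
    coll = GeneSetCollection(sets, set(diff.index))
    mi = page_mi(labels, coll, min_size=5, max_size=300, nperm=500, seed=2)
    mi.to_csv(OUT / "page_mi_motif_sets.tsv", sep="\t")
    n_sig = int(mi["significant"].sum())
    print(f"MI analysis: {n_sig} of {len(mi)} motif sets informative about "
          "the differential call at p < 0.005")


if __name__ == "__main__":
    main()
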