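"""Repertoire diversity across genotypes.

Computes Shannon (q=1) and Simpson (q=2) Hill diversities and the
Productive Simpson Clonality for each genotype's clone table.  The
generator plants an evenness gradient WT > C > K > CK, so clonality
should increase (and diversity decrease) along that order.

Run after 01_simulate.py.
"""

from pathlib import Path

import pandas as pd

from gcbreg.clonality import clonal_fraction_curve, diversity_summary

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    rows = {}
    for g in ("WT", "C", "K", "CK"):
        counts = pd.read_csv(DATA / f"clones_{g}.tsv", sep="\t", index_col=0)["count"]
        rows[g] = diversity_summary(counts.values)
        curve = clonal_fraction_curve(counts.values)
        top10 = curve[min(9, len(curve) - 1)]
        rows[g]["top10_clone_fraction"] = top10
    table = pd.DataFrame(rows).T
    table.to_csv(OUT / "clonality_by_genotype.tsv", sep="\t")
    print(table.round(3).to_string())
    print("clonality ordering:",
          " < ".join(table["clonality"].sort_values().index))


if __name__ == "__main__":
    main()
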