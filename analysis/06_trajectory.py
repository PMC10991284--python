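"""Trajectory clustering of per-peak fold-change profiles.

Builds log2FC profiles (each mutant genotype vs WT) from VST-normalized
counts, selects the fuzzifier by the minimal-fuzzifier rule, clusters
with fuzzy c-means, and fits the cell-type x genotype interaction model
to a synthetic CB/CC expression contrast for one cluster.

Run after 02_differential_peaks.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gcbreg import io as gio
from gcbreg.differential import PeakCountMatrix, size_factors, vst_like
from gcbreg.trajectory import (
    fuzzy_cmeans,
    hard_assignments,
    select_fuzzifier,
    traj_linear_model,
)

DATA = Path("results/data")
OUT = Path("results")
SEED = 20240901


def main() -> None:
    counts = gio.read_counts_tsv(DATA / "peak_counts.tsv")
    groups = gio.read_sample_sheet(DATA / "samples.tsv")
    pcm = PeakCountMatrix(counts, groups)
    sf = size_factors(counts)
    vst = vst_like(counts, sf)

    prof = pd.DataFrame({
        g: vst[pcm.samples_in(g)].mean(axis=1)
        - vst[pcm.samples_in("WT")].mean(axis=1)
        for g in ("C", "K", "CK")
    })
    m = select_fuzzifier(prof.shape[0], prof.shape[1])
    fit = fuzzy_cmeans(prof.values, c=4, m=m, seed=SEED)
    member = pd.DataFrame(
        fit.membership, index=prof.index,
        columns=[f"cluster_{i}" for i in range(4)],
    )
    member["hard"] = hard_assignments(fit)
    member.to_csv(OUT / "trajectory_membership.tsv", sep="\t")
    print(f"fuzzifier m = {m:.3f} (N={prof.shape[0]}, D={prof.shape[1]}); "
          f"objective {fit.objective:.1f} after {fit.n_iter} iterations")
    sizes = member["hard"].value_counts().sort_index()
    print("hard cluster sizes:", dict(sizes))

    # interaction model on a synthetic CB/CC contrast for the largest cluster
    biggest = int(sizes.drop(-1, errors="ignore").idxmax())
    genes_in = member.index[member["hard"] == biggest][:50]
    rng = np.random.default_rng(SEED)
    conds = [(ct, gt) for ct in ("CB", "CC") for gt in ("C", "K", "CK")]
    effect = {
        (ct, gt): 0.2 * (ct == "CC") - 0.4 * (gt == "CK") - 0.3 * (ct == "CC") * (gt == "CK")
        for ct, gt in conds
    }
    mat = pd.DataFrame(
        [[effect[c] + rng.normal(0, 0.3) for c in conds] for _ in genes_in],
        index=genes_in, columns=[f"{a}_{b}" for a, b in conds],
    )
    model = traj_linear_model(mat, [c[0] for c in conds], [c[1] for c in conds])
    model.to_csv(OUT / "trajectory_interaction_model.tsv", sep="\t")
    print("interaction model (CC:CK) coef "
          f"{model.loc['cell_type[CC]:genotype[CK]', 'coef']:+.3f} "
          f"(p {model.loc['cell_type[CC]:genotype[CK]', 'p']:.3g})")


if __name__ == "__main__":
    main()
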