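"""Single-cell signature analytics along pseudotime.

Module scores follow the bin-matched control construction: genes are
binned by average expression, each signature gene draws control genes
from its own bin, and the per-cell score is mean signature expression
minus mean control expression — so depth and coverage effects cancel.
Pseudotime distribution shifts between genotypes are tested by Wilcoxon
rank-sum; the decile procedure splits pooled pseudotime into 10
quantile bins, tests signature scores between genotypes within each
bin (BH across bins), and reports the difference of per-genotype
smoothing splines at the bin midpoints (the delta-spline readout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .differential import bh_adjust

__all__ = [
    "CellTable",
    "module_score",
    "pseudotime_shift_test",
    "fit_delta_spline",
    "decile_delta",
]


@dataclass
class CellTable:
    """Cells with genotype, pseudotime in [0, 1], and expression."""

    cells: pd.DataFrame  # index cell_id; columns genotype, pseudotime
    expression: pd.DataFrame  # cells x genes, normalized log counts

    def __post_init__(self) -> None:
        req = {"genotype", "pseudotime"}
        if not req <= set(self.cells.columns):
            raise ValueError(f"cell table needs columns {req}")
        pt = self.cells["pseudotime"]
        if not np.isfinite(pt).all():
            raise ValueError("pseudotime must be finite")
        if not self.cells.index.equals(self.expression.index):
            raise ValueError("cells and expression must share the cell index")

    def rescaled(self) -> "CellTable":
        """Pseudotime min-max rescaled to [0, 1]."""
        pt = self.cells["pseudotime"]
        span = pt.max() - pt.min()
        cells = self.cells.copy()
        cells["pseudotime"] = (pt - pt.min()) / span if span > 0 else 0.0
        return CellTable(cells, self.expression)


def module_score(
    expr: pd.DataFrame,
    signature_genes: Sequence[str],
    n_ctrl: int = 5,
    n_bins: int = 24,
    seed: int = 0,
) -> pd.Series:
    """Per-cell signature score with expression-bin-matched controls.

    Genes are cut into ``n_bins`` bins of equal gene count by average
    expression; for each signature gene, ``n_ctrl`` control genes are
    sampled (without replacement where possible, excluding signature
    genes where possible) from its bin.  Score = mean signature
    expression - mean control expression.
    """
    signature = [g for g in signature_genes]
    missing = set(signature) - set(expr.columns)
    if missing:
        raise ValueError(f"signature genes absent from expression: {sorted(missing)}")
    if n_bins > expr.shape[1]:
        raise ValueError("n_bins exceeds the number of genes")
    rng = np.random.default_rng(seed)

    avg = expr.mean(axis=0)
    # rank-based binning keeps bins equally sized under ties
    ranks = avg.rank(method="first") - 1
    bins = np.floor(ranks * n_bins / len(avg)).astype(int)

    controls: list[str] = []
    sig_set = set(signature)
    for g in signature:
        pool = [x for x in avg.index[bins == bins[g]] if x not in sig_set]
        if len(pool) >= n_ctrl:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            pool = list(avg.index[bins == bins[g]])
            if len(pool) >= n_ctrl:
                chosen = rng.choice(pool, size=n_ctrl, replace=False)
            else:
                warnings.warn(
                    f"bin of gene {g} smaller than n_ctrl; sampling with replacement"
                )
                chosen = rng.choice(pool, size=n_ctrl, replace=True)
        controls.extend(chosen)

    score = expr[signature].mean(axis=1) - expr[controls].mean(axis=1)
    score.name = "module_score"
    return score


def pseudotime_shift_test(
    cells: CellTable, group_a: str, group_b: str
) -> tuple[float, float]:
    """Wilcoxon rank-sum on pseudotime between two genotypes.

    Exact enumeration when both groups have <= 8 cells and no ties;
    tie-corrected normal approximation otherwise.  Returns the
    Mann-Whitney U statistic for group_a and the two-sided p.
    """
    pt = cells.cells["pseudotime"]
    a = pt[cells.cells["genotype"] == group_a].values
    b = pt[cells.cells["genotype"] == group_b].values
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def fit_delta_spline(
    x: np.ndarray,
    y: np.ndarray,
    eval_at: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """Cubic smoothing spline fit of y vs x, evaluated at ``eval_at``.

    Duplicate x values are averaged; the smoothing factor is selected
    from a small grid by generalized cross-validation with effective
    degrees of freedom approximated from the knot count.
    """
    df = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True)["y"].mean()
    xs, ys = df.index.values, df.values
    n = xs.size
    if n <= k:
        # too few distinct pseudotime values for a cubic: fall back to mean
        return np.full(len(eval_at), ys.mean())
    base = n * np.var(ys) if np.var(ys) > 0 else 1.0
    best_spl, best_gcv = None, np.inf
    for factor in (0.05, 0.1, 0.25, 0.5, 1.0, 2.0):
        try:
            spl = UnivariateSpline(xs, ys, k=k, s=factor * base)
        except Exception:
            continue
        resid = ys - spl(xs)
        edf = len(spl.get_knots()) + k - 1
        if edf >= n:
            continue
        gcv = n * np.sum(resid**2) / (n - edf) ** 2
        if gcv < best_gcv:
            best_gcv, best_spl = gcv, spl
    if best_spl is None:
        best_spl = UnivariateSpline(xs, ys, k=k, s=n * base)
    return best_spl(eval_at)


def decile_delta(
    cells: CellTable,
    scores: pd.Series,
    reference_genotype: str,
    test_genotype: str,
    n_deciles: int = 10,
) -> pd.DataFrame:
    """Per-decile Wilcoxon test of signature scores plus delta splines.

    Decile boundaries come from pooled pseudotime quantiles over both
    genotypes.  In each decile, scores are compared between genotypes
    by Wilcoxon rank-sum (p = None when a genotype is absent from the
    decile); BH across the testable deciles.  The delta column is the
    test-genotype smoothing spline minus the reference spline,
    evaluated at decile midpoints.
    """
    ct = cells.rescaled()
    mask = ct.cells["genotype"].isin([reference_genotype, test_genotype])
    sub = ct.cells[mask]
    sc = scores[sub.index]
    if len(sub) < n_deciles:
        raise ValueError("need at least n_deciles cells across both genotypes")
    pt = sub["pseudotime"].values
    qs = np.quantile(pt, np.linspace(0, 1, n_deciles + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    decile = np.clip(np.searchsorted(qs, pt, side="right") - 1, 0, n_deciles - 1)

    is_test = (sub["genotype"] == test_genotype).values
    mids = []
    rows = []
    finite_qs = np.quantile(pt, np.linspace(0, 1, n_deciles + 1))
    for d in range(n_deciles):
        in_d = decile == d
        a = sc.values[in_d & is_test]
        b = sc.values[in_d & ~is_test]
        mids.append((finite_qs[d] + finite_qs[d + 1]) / 2)
        if a.size == 0 or b.size == 0:
            rows.append({"p": np.nan, "n_test": a.size, "n_ref": b.size})
            continue
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
            )
        rows.append({"p": p, "n_test": a.size, "n_ref": b.size})

    out = pd.DataFrame(rows, index=pd.RangeIndex(1, n_deciles + 1, name="decile"))
    out["boundary_lo"] = finite_qs[:-1]
    out["boundary_hi"] = finite_qs[1:]
    testable = out["p"].notna()
    out["padj"] = np.nan
    if testable.any():
        out.loc[testable, "padj"] = bh_adjust(out.loc[testable, "p"].values)

    mids = np.asarray(mids)
    ref_spline = fit_delta_spline(pt[~is_test], sc.values[~is_test], mids)
    test_spline = fit_delta_spline(pt[is_test], sc.values[is_test], mids)
    out["delta"] = test_spline - ref_spline
    return out
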