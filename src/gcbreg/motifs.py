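"""Multivariate TF regulatory-potential model.

Per-peak accessibility log2 fold-change is regressed on boolean motif
presence plus GC content:

    log2FC ~ b0 + x1*b1 + ... + xn*bn + GC*bGC

by ordinary least squares with heteroskedasticity-consistent (sandwich)
standard errors.  Each motif's coefficient is its accessibility
remodeling score in log2FC units; p-values are two-sided t on the
residual degrees of freedom, BH-adjusted across motif terms only (the
intercept and GC covariate are nuisance terms, not hypotheses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .differential import bh_adjust

__all__ = ["DesignInfo", "build_design", "fit_remodeling_model", "scan_pwm"]


@dataclass
class DesignInfo:
    """Design matrix plus a record of dropped/aliased motif columns."""

    X: pd.DataFrame
    motif_columns: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)


def build_design(motifs: pd.DataFrame, gc: np.ndarray) -> DesignInfo:
    """Assemble [intercept | motifs | GC], dropping degenerate columns.

    Zero-variance motif columns are dropped with reason recorded; exact
    duplicate columns collapse onto the first occurrence with an alias
    entry.  Raises if the remaining design is rank-deficient, listing
    the collinear columns.
    """
    gc = np.asarray(gc, dtype=float)
    if motifs.shape[0] != gc.shape[0]:
        raise ValueError("motifs and gc must cover the same peaks")
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    vals = motifs.values
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("motif matrix must be boolean (0/1)")
    if motifs.columns.has_duplicates:
        raise ValueError("motif ids must be unique")

    dropped: dict[str, str] = {}
    aliases: dict[str, str] = {}
    keep: list[str] = []
    seen: dict[bytes, str] = {}
    for m in motifs.columns:
        col = motifs[m].values.astype(np.int8)
        if col.min() == col.max():
            dropped[m] = "zero variance"
            continue
        key = col.tobytes()
        if key in seen:
            aliases[m] = seen[key]
            continue
        seen[key] = m
        keep.append(m)

    X = pd.DataFrame({"intercept": np.ones(len(gc))})
    for m in keep:
        X[m] = motifs[m].values.astype(float)
    X["GC"] = gc
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        raise ValueError(
            "design matrix rank-deficient after drops; collinear columns "
            f"among {list(X.columns)}"
        )
    return DesignInfo(X=X, motif_columns=keep, dropped=dropped, aliases=aliases)


def fit_remodeling_model(
    y: np.ndarray, design: DesignInfo, cov_type: str = "HC1"
) -> pd.DataFrame:
    """OLS with sandwich covariance; per-motif effect table.

    Returns one row per design column with beta, robust SE, t, p and —
    for motif terms only — BH-adjusted p.  Dropped motifs appear with
    their reason and NaN statistics so no input motif silently vanishes.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and design must have equal rows")
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need more peaks than coefficients")
    if cov_type not in ("HC0", "HC1", "HC2", "HC3"):
        raise ValueError(f"unsupported cov_type {cov_type!r}")

    fit = sm.OLS(y, X.values).fit(cov_type=cov_type)
    # two-sided t on residual df (statsmodels uses normal for HC by default
    # in some versions; recompute explicitly for a fixed contract)
    from scipy import stats as _st

    df_resid = int(fit.df_resid)
    se = fit.bse
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, fit.params / se, np.inf * np.sign(fit.params))
    pvals = 2 * _st.t.sf(np.abs(tvals), df_resid)
    pvals = np.where(se > 0, pvals, 0.0)

    table = pd.DataFrame(
        {"beta": fit.params, "se": se, "t": tvals, "p": pvals},
        index=X.columns,
    )
    motif_rows = design.motif_columns
    table["padj"] = np.nan
    if motif_rows:
        table.loc[motif_rows, "padj"] = bh_adjust(table.loc[motif_rows, "p"].values)
    table["status"] = "fit"
    for m, reason in design.dropped.items():
        table.loc[m] = {"beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                        "padj": np.nan, "status": f"dropped: {reason}"}
    for m, target in design.aliases.items():
        table.loc[m] = {"beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                        "padj": np.nan, "status": f"alias of {target}"}
    return table


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_pwm(
    sequences: Sequence[str],
    pwm: np.ndarray,
    threshold: float,
    background: Optional[np.ndarray] = None,
    motif_id: str = "motif",
) -> pd.DataFrame:
    """Boolean presence of a PWM hit (either strand) per sequence.

    ``pwm`` is a 4 x L probability matrix over A, C, G, T.  A sequence
    is a hit when any window on either strand scores at least
    ``threshold`` log-odds bits against ``background`` (uniform by
    default).  Convenience scanner; the main pipeline consumes a
    precomputed motif matrix.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("pwm must be 4 x L (rows A, C, G, T)")
    L = pwm.shape[1]
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    logodds = np.log2(np.maximum(pwm, 1e-9) / background[:, None])
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def best_score(seq: str) -> float:
        if len(seq) < L:
            return -np.inf
        best = -np.inf
        for strand_seq in (seq, _revcomp(seq)):
            idx = np.fromiter((base_idx[b] for b in strand_seq), dtype=int)
            for i in range(len(seq) - L + 1):
                s = logodds[idx[i : i + L], np.arange(L)].sum()
                best = max(best, s)
        return best

    present = []
    for seq in sequences:
        seq = seq.upper()
        if any(b not in base_idx for b in seq):
            raise ValueError("sequences must be over the DNA alphabet ACGT")
        present.append(int(best_score(seq) >= threshold))
    return pd.DataFrame({motif_id: present})
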