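"""Trajectory clustering of per-gene log2FC profiles across the
centroblast-to-centrocyte (CB->CC) transition, and the per-cluster
linear model with cell-type x genotype interaction.

Fuzzy c-means (Bezdek's alternating updates) groups genes by the shape
of their expression change across the six conditions (2 cell types x 3
mutant genotypes, as log2FC against wild-type CB); the fuzzifier m is
selected by the Schwaemmle-Jensen minimal-fuzzifier rule, which
prescribes the smallest m at which random (structure-free) data stops
producing spurious hard clusters, as a function of dimensionality D and
object count N:

    m(D, N) = 1 + (1418/N + 22.05) * D^-2
                + (12.33/N + 0.243) * D^(-0.0406 ln N - 0.1134)

Each cluster's mean profile is then modeled by OLS as
log2FC ~ cell_type + genotype + cell_type:genotype with treatment
coding (references CB and the CREBBP-mutant genotype C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist

__all__ = [
    "FuzzyClusters",
    "select_fuzzifier",
    "fuzzy_cmeans",
    "hard_assignments",
    "traj_linear_model",
]

CELL_TYPES = ("CB", "CC")
GENOTYPES = ("C", "K", "CK")


def select_fuzzifier(n_genes: int, n_dims: int) -> float:
    """Minimal fuzzifier for (N objects, D dimensions); always > 1."""
    if n_genes < 2 or n_dims < 1:
        raise ValueError("need n_genes >= 2 and n_dims >= 1")
    N, D = float(n_genes), float(n_dims)
    return 1.0 + (1418.0 / N + 22.05) * D ** -2 + (
        12.33 / N + 0.243
    ) * D ** (-0.0406 * np.log(N) - 0.1134)


@dataclass
class FuzzyClusters:
    centroids: np.ndarray  # c x dims
    membership: np.ndarray  # n x c, rows sum to 1
    fuzzifier: float
    objective: float
    n_iter: int
    objective_trace: list


def _fcm_once(
    X: np.ndarray, c: int, m: float, tol: float, max_iter: int, rng: np.random.Generator
) -> FuzzyClusters:
    n = X.shape[0]
    u = rng.dirichlet(np.ones(c), size=n)
    exponent = 2.0 / (m - 1.0)
    trace = []
    prev_u = u
    for it in range(1, max_iter + 1):
        um = prev_u ** m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        d = cdist(X, centroids)
        zero = d < 1e-12
        if zero.any():
            u = np.zeros_like(d)
            rows = zero.any(axis=1)
            # coincident point: full membership to (first) coincident centroid
            u[rows, np.argmax(zero[rows], axis=1)] = 1.0
            inv = d[~rows] ** -exponent
            u[~rows] = inv / inv.sum(axis=1, keepdims=True)
        else:
            inv = d ** -exponent
            u = inv / inv.sum(axis=1, keepdims=True)
        obj = float(((u ** m) * d ** 2).sum())
        trace.append(obj)
        if np.max(np.abs(u - prev_u)) < tol:
            prev_u = u
            break
        prev_u = u
    return FuzzyClusters(centroids, prev_u, m, trace[-1], len(trace), trace)


def fuzzy_cmeans(
    X: np.ndarray,
    c: int = 8,
    m: Optional[float] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    n_init: int = 5,
) -> FuzzyClusters:
    """Fuzzy c-means, best of ``n_init`` seeded restarts by objective."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < c:
        raise ValueError("need a 2-D matrix with at least c rows")
    if m is None:
        m = select_fuzzifier(X.shape[0], X.shape[1])
    if m <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        fit = _fcm_once(X, c, m, tol, max_iter, rng)
        if best is None or fit.objective < best.objective:
            best = fit
    return best


def hard_assignments(clusters: FuzzyClusters, min_membership: float = 0.3) -> np.ndarray:
    """Argmax membership; genes below ``min_membership`` get -1."""
    lab = clusters.membership.argmax(axis=1)
    lab[clusters.membership.max(axis=1) < min_membership] = -1
    return lab


def traj_linear_model(
    log2fc: pd.DataFrame,
    cell_type: Sequence[str],
    genotype: Sequence[str],
) -> pd.DataFrame:
    """Pooled OLS of cluster gene log2FC on cell type, genotype, interaction.

    ``log2fc`` is genes x conditions; ``cell_type`` and ``genotype``
    label the condition columns.  Observations are all gene x condition
    values.  Treatment coding with references CB and C gives
    coefficients: intercept, CC, K, CK, CC:K, CC:CK, each with a
    classical two-sided t p-value.  A single-gene cluster is rejected
    (6 observations cannot support 6 coefficients).
    """
    cell_type = list(cell_type)
    genotype = list(genotype)
    if log2fc.shape[1] != len(cell_type) or log2fc.shape[1] != len(genotype):
        raise ValueError("condition labels must match log2fc columns")
    if set(zip(cell_type, genotype)) != {
        (ct, gt) for ct in CELL_TYPES for gt in GENOTYPES
    }:
        raise ValueError(
            "all six conditions (CB/CC x C/K/CK) must be present exactly"
        )
    n_genes = log2fc.shape[0]
    if n_genes < 1:
        raise ValueError("empty cluster")
    if n_genes * log2fc.shape[1] <= 6:
        raise ValueError(
            "cluster too small: pooled fit needs more observations than "
            "the 6 model coefficients"
        )

    y = log2fc.values.ravel()  # gene-major
    cols = {"intercept": np.ones(log2fc.shape[1])}
    is_cc = np.array([ct == "CC" for ct in cell_type], dtype=float)
    cols["cell_type[CC]"] = is_cc
    for gt in ("K", "CK"):
        ind = np.array([g == gt for g in genotype], dtype=float)
        cols[f"genotype[{gt}]"] = ind
        cols[f"cell_type[CC]:genotype[{gt}]"] = is_cc * ind
    X_cond = pd.DataFrame(cols)
    X = pd.concat([X_cond] * n_genes, ignore_index=True)

    fit = sm.OLS(y, X.values).fit()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        },
        index=X_cond.columns,
    ).assign(df_resid=int(fit.df_resid))
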