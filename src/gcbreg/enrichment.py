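"""Enrichment statistics: Fisher odds ratios, hypergeometric
over-representation, preranked GSEA, and information-theoretic
(mutual-information) pathway analysis.

The GSEA implementation follows the weighted Kolmogorov-Smirnov running
sum with a gene-label permutation null, per-sign normalized enrichment
scores, and the standard NES-based FDR across sets.  The
mutual-information analysis scores each pathway by I(membership;
cluster) in bits over the gene universe and assesses significance by
label permutation, with per-cluster hypergeometric over/under
representation for pathways passing the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "fisher_exact_or",
    "hypergeom_enrich",
    "gsea_es",
    "gsea_preranked",
    "page_mi",
    "mutual_information_bits",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.sets = {name: set(g) & self.universe for name, g in self.sets.items()}

    def filtered(self, min_size: int, max_size: int) -> dict[str, set[str]]:
        return {
            n: s for n, s in self.sets.items() if min_size <= len(s) <= max_size
        }


def fisher_exact_or(table) -> tuple[float, float]:
    """Sample odds ratio ad/bc and two-sided Fisher exact p.

    Zero cells give an infinite or zero odds ratio; the p-value sums
    hypergeometric probabilities no larger than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = t.astype(int)
    a, b, c, d = t.ravel()
    if b * c > 0:
        odds = (a * d) / (b * c)  # 0 when a zero cell sits on the diagonal
    elif a * d > 0:
        odds = np.inf
    else:
        odds = np.nan
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def hypergeom_enrich(hits: int, set_size: int, draw_size: int, universe_size: int) -> float:
    """Upper-tail P(X >= hits) for over-representation."""
    if not (0 <= hits <= min(set_size, draw_size)):
        raise ValueError("hits must lie in [0, min(set_size, draw_size)]")
    if max(set_size, draw_size) > universe_size:
        raise ValueError("set and draw must fit in the universe")
    return float(stats.hypergeom.sf(hits - 1, universe_size, set_size, draw_size))


def gsea_es(
    scores: np.ndarray,
    in_set: np.ndarray,
    weight: float = 1.0,
) -> tuple[float, int, np.ndarray]:
    """Enrichment score of one set against a descending-ranked list.

    ``scores`` must be sorted descending; ``in_set`` is a boolean mask
    in the same order.  Hits increment the running sum by
    |score|^weight (normalized), misses decrement by 1/(N - n_set).
    Returns (ES, index of the extremum, running sum).
    """
    scores = np.asarray(scores, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    N = scores.size
    n_set = int(in_set.sum())
    if n_set == 0:
        raise ValueError("set has empty intersection with the ranked list")
    if n_set == N:
        raise ValueError("set equals the whole ranked list")
    w = np.abs(scores) ** weight
    hit_total = w[in_set].sum()
    if hit_total == 0:  # all hit scores zero: fall back to unweighted steps
        incr = in_set / n_set
    else:
        incr = np.where(in_set, w / hit_total, 0.0)
    decr = np.where(in_set, 0.0, 1.0 / (N - n_set))
    running = np.cumsum(incr - decr)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), i_ext, running


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: Mapping[str, set],
    weight: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` maps gene -> score; genes are sorted by descending score
    (ties broken by gene id for reproducibility).  For each set: ES from
    the weighted running sum; a null of ``nperm`` random same-size
    label sets; NES = ES / mean |null ES| of matching sign; p = fraction
    of same-sign null ES at least as extreme; FDR q by the standard
    NES-ratio procedure across all sets and permutations.  Returns a
    DataFrame indexed by set name with es, nes, p, fdr_q, n_genes and
    the leading-edge gene list.
    """
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    scores = ranked[order].values.astype(float)
    genes = np.array(order)
    N = len(genes)
    rng = np.random.default_rng(seed)

    rows = {}
    null_nes_all: list[np.ndarray] = []
    obs_nes = {}
    for name, gset in gene_sets.items():
        mask = np.isin(genes, list(gset))
        es, i_ext, _ = gsea_es(scores, mask, weight)
        n_set = int(mask.sum())
        null_es = np.empty(nperm)
        for b in range(nperm):
            perm_mask = np.zeros(N, dtype=bool)
            perm_mask[rng.choice(N, size=n_set, replace=False)] = True
            null_es[b], _, _ = gsea_es(scores, perm_mask, weight)
        same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same.size == 0:
            p = 1.0 / (nperm + 1)
            nes = 0.0
            null_nes = np.zeros(0)
        else:
            p = (np.sum(np.abs(same) >= abs(es)) + 1) / (same.size + 1)
            denom = np.mean(np.abs(same))
            nes = es / denom if denom > 0 else 0.0
            pos = null_es[null_es > 0]
            neg = null_es[null_es < 0]
            null_nes = np.concatenate([
                pos / pos.mean() if pos.size else np.zeros(0),
                neg / np.abs(neg).mean() if neg.size else np.zeros(0),
            ])
        if es >= 0:
            lead = genes[: i_ext + 1][mask[: i_ext + 1]]
        else:
            lead = genes[i_ext:][mask[i_ext:]]
        rows[name] = {
            "es": es,
            "nes": nes,
            "p": p,
            "n_genes": n_set,
            "leading_edge": ",".join(lead),
        }
        obs_nes[name] = nes
        null_nes_all.append(null_nes)

    # NES-based FDR: q(set) = [frac(null |NES| >= |NES|)] / [frac(obs |NES| >= |NES|)]
    all_null = np.concatenate(null_nes_all) if null_nes_all else np.zeros(0)
    obs_vals = np.array(list(obs_nes.values()))
    for name in rows:
        nes = obs_nes[name]
        if all_null.size == 0 or nes == 0:
            rows[name]["fdr_q"] = 1.0
            continue
        if nes > 0:
            num = np.mean(all_null[all_null > 0] >= nes) if (all_null > 0).any() else 0.0
            den = np.mean(obs_vals[obs_vals > 0] >= nes) if (obs_vals > 0).any() else 1.0
        else:
            num = np.mean(all_null[all_null < 0] <= nes) if (all_null < 0).any() else 0.0
            den = np.mean(obs_vals[obs_vals < 0] <= nes) if (obs_vals < 0).any() else 1.0
        rows[name]["fdr_q"] = float(min(1.0, num / max(den, 1e-12)))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "set"
    return df


def mutual_information_bits(membership: np.ndarray, labels: np.ndarray) -> float:
    """I(membership; cluster label) in bits over the universe."""
    membership = np.asarray(membership, dtype=bool)
    labels = np.asarray(labels)
    n = membership.size
    if n == 0:
        raise ValueError("empty universe")
    mi = 0.0
    for m in (False, True):
        pm = np.mean(membership == m)
        if pm == 0:
            continue
        for c in np.unique(labels):
            joint = np.mean((membership == m) & (labels == c))
            pc = np.mean(labels == c)
            if joint > 0:
                mi += joint * np.log2(joint / (pm * pc))
    return max(0.0, mi)


def page_mi(
    cluster_labels: Mapping[str, object],
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 300,
    alpha: float = 0.005,
    nperm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Information-theoretic pathway analysis over discrete gene groups.

    Pathways outside [min_size, max_size] (after restriction to the
    universe) are excluded.  For each remaining pathway the MI between
    its binary membership and the cluster label is computed over the
    universe; p is the fraction of ``nperm`` label permutations with MI
    at least the observed.  Pathways with p < alpha are reported with
    per-cluster hypergeometric over-representation p (and the depletion
    tail), all pathways with their MI and p.
    """
    genes = sorted(cluster_labels)
    if not genes:
        raise ValueError("empty universe")
    labels = np.array([cluster_labels[g] for g in genes])
    rng = np.random.default_rng(seed)
    eligible = collection.filtered(min_size, max_size)

    perms = [rng.permutation(labels) for _ in range(nperm)]
    rows = {}
    for name, gset in eligible.items():
        member = np.array([g in gset for g in genes])
        mi = mutual_information_bits(member, labels)
        null_ge = sum(
            1 for pl in perms if mutual_information_bits(member, pl) >= mi
        )
        p = (null_ge + 1) / (nperm + 1)
        row = {"mi_bits": mi, "p": p, "n_genes": int(member.sum()),
               "significant": p < alpha}
        if p < alpha:
            draw = int(member.sum())
            for c in np.unique(labels):
                in_c = int(np.sum(member & (labels == c)))
                size_c = int(np.sum(labels == c))
                row[f"p_over_{c}"] = hypergeom_enrich(
                    in_c, size_c, draw, len(genes)
                )
                row[f"p_under_{c}"] = float(
                    stats.hypergeom.cdf(in_c, len(genes), size_c, draw)
                )
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "pathway"
    return df
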