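"""ROSE super-enhancer calling and differential super-enhancer activity.

Super-enhancers are stitched enhancer clusters whose aggregate signal
separates from typical enhancers at the point of the ranked signal
curve where the tangent slope reaches 1: with regions sorted by
ascending signal and both rank and signal scaled to [0, 1], the cutoff
sits at the region maximizing (scaled rank - scaled signal); regions
strictly above the cutoff signal are super.

Differential activity follows the constituent-summation procedure:
every accessibility peak overlapping a super-enhancer by at least 1 bp
contributes its counts to that super-enhancer (maximal overlap decides
multi-hits), and the summed counts are normalized with size factors
computed genome-wide from the full peak matrix, not from the
super-enhancer sums, so read-depth correction is not distorted by the
regions under test.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    assign_to_tads,
    stitch,
)

__all__ = [
    "rose_cutoff_index",
    "rose_call",
    "se_sum_constituents",
    "se_differential",
    "link_se_to_genes",
]


def rose_cutoff_index(signals: np.ndarray) -> Optional[int]:
    """Index (in ascending sort order) of the tangent cutoff region.

    Returns None when all signals are equal (no cutoff exists).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n < 2 or s[0] == s[-1]:
        return None
    scaled_rank = np.arange(n) / (n - 1)
    scaled_signal = (s - s[0]) / (s[-1] - s[0])
    return int(np.argmax(scaled_rank - scaled_signal))


def rose_call(
    peaks: Sequence[GenomicInterval],
    signal: np.ndarray,
    genes: Sequence[GeneAnnotation],
    stitch_gap: int = 12_500,
    tss_exclusion: int = 2_500,
) -> pd.DataFrame:
    """Call super-enhancers from peaks with per-sample signal.

    Peaks whose center lies within ``tss_exclusion`` bp of any TSS are
    removed, survivors are stitched with ``stitch_gap``, and stitched
    regions are ranked by total signal (summed over constituent peaks,
    averaged across samples when ``signal`` is 2-D).  Regions with
    signal strictly above the tangent cutoff are flagged super.

    Returns a DataFrame with one row per stitched region: chrom, start,
    end, constituent peak indices (into the input list), signal, rank
    (1 = highest signal), is_super, cutoff_signal.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 2:
        peak_signal = signal.mean(axis=1)
    else:
        peak_signal = signal
    if len(peak_signal) != len(peaks):
        raise ValueError("signal length must match number of peaks")

    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.asarray(v, dtype=float) for c, v in tss_by_chrom.items()}

    keep: list[int] = []
    for i, pk in enumerate(peaks):
        tss = tss_by_chrom.get(pk.chrom)
        if tss is not None and tss.size and np.min(np.abs(tss - pk.center)) <= tss_exclusion:
            continue
        keep.append(i)

    kept_peaks = [peaks[i] for i in keep]
    regions = stitch(kept_peaks, stitch_gap)

    rows = []
    for r in regions:
        members = [keep[j] for j in r.members]
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "members": members,
                "signal": float(sum(peak_signal[m] for m in members)),
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "members", "signal"])
    if df.empty:
        df["rank"] = df["is_super"] = df["cutoff_signal"] = []
        return df

    cut = rose_cutoff_index(df["signal"].values)
    if cut is None:
        warnings.warn("all stitched signals equal; no super-enhancer cutoff exists")
        df["cutoff_signal"] = np.nan
        df["is_super"] = False
    else:
        cutoff_signal = float(np.sort(df["signal"].values)[cut])
        df["cutoff_signal"] = cutoff_signal
        df["is_super"] = df["signal"] > cutoff_signal
    # rank 1 = strongest; ties broken by position for determinism
    order = df.sort_values(["signal", "chrom", "start"], ascending=[False, True, True]).index
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    df.index = [f"SE_{i}" for i in range(len(df))]
    df.index.name = "se_id"
    return df


def se_sum_constituents(
    se_table: pd.DataFrame,
    peak_intervals: Sequence[GenomicInterval],
    counts: pd.DataFrame,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Sum constituent peak counts per super-enhancer region.

    A count-matrix peak is a constituent of a region iff it overlaps by
    at least ``min_overlap`` bp; a peak overlapping several regions is
    assigned to the one of maximal overlap (ties to the first region in
    table order), so each peak contributes at most once.
    """
    if len(peak_intervals) != counts.shape[0]:
        raise ValueError("peak_intervals must parallel counts rows")
    se_ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in se_table.itertuples()
    ]
    sums = pd.DataFrame(
        0.0, index=se_table.index, columns=counts.columns
    )
    for p_idx, pk in enumerate(peak_intervals):
        best_se, best_ov = None, 0
        for se_id, siv in zip(se_table.index, se_ivs):
            ov = pk.overlap_length(siv)
            if ov > best_ov:
                best_se, best_ov = se_id, ov
        if best_se is not None and best_ov >= min_overlap:
            sums.loc[best_se] += counts.iloc[p_idx].values
    return sums


def se_differential(
    se_counts: pd.DataFrame,
    genome_wide_size_factors: pd.Series,
    groups: dict[str, str],
    reference_group: str,
    pseudocount: float = 0.5,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Ranked waterfall of super-enhancer log2 fold-changes.

    ``genome_wide_size_factors`` must come from the full peak matrix.
    Returns per-SE normalized group means, log2FC of every non-reference
    group pooled vs reference, ascending rank (the waterfall order), and
    a ``closing`` flag at log2FC < -log2(fc_threshold).
    """
    if not genome_wide_size_factors.index.equals(se_counts.columns):
        if set(genome_wide_size_factors.index) != set(se_counts.columns):
            raise ValueError("size-factor vector does not match sample columns")
        genome_wide_size_factors = genome_wide_size_factors[se_counts.columns]
    norm = se_counts / genome_wide_size_factors
    ref = [s for s in se_counts.columns if groups[s] == reference_group]
    tst = [s for s in se_counts.columns if groups[s] != reference_group]
    if not ref or not tst:
        raise ValueError("need samples in and out of the reference group")
    log2fc = np.log2(
        (norm[tst].mean(axis=1) + pseudocount) / (norm[ref].mean(axis=1) + pseudocount)
    )
    out = pd.DataFrame({"log2FC": log2fc})
    out["closing"] = out["log2FC"] < -np.log2(fc_threshold)
    order = out.sort_values(["log2FC"], kind="stable").index
    # stable sort keeps se_id order among ties
    out.loc[order, "rank"] = np.arange(1, len(out) + 1)
    out["rank"] = out["rank"].astype(int)
    return out.sort_values("rank")


def link_se_to_genes(
    se_table: pd.DataFrame,
    tads: dict[str, GenomicInterval],
    genes: Sequence[GeneAnnotation],
    diff_genes: Optional[pd.DataFrame] = None,
) -> dict[str, list[tuple[str, str]]]:
    """Link each super-enhancer to the genes of its TAD.

    A region maps to the TAD of maximal overlap; linked genes are those
    whose TSS falls inside that TAD.  Each linked gene carries its
    differential call from ``diff_genes`` ('ns' when absent).  Regions
    outside all TADs link to an empty list.
    """
    se_ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in se_table.itertuples()
    ]
    se_tad = assign_to_tads(se_ivs, tads)
    gene_tad = assign_to_tads(list(genes), tads)
    genes_by_tad: dict[str, list[GeneAnnotation]] = {}
    for gi, tid in gene_tad.items():
        if tid is not None:
            genes_by_tad.setdefault(tid, []).append(genes[gi])

    links: dict[str, list[tuple[str, str]]] = {}
    for i, se_id in enumerate(se_table.index):
        tid = se_tad[i]
        linked = []
        for g in genes_by_tad.get(tid, []) if tid is not None else []:
            if diff_genes is not None and g.gene_id in diff_genes.index:
                call = str(diff_genes.loc[g.gene_id, "call"])
            else:
                call = "ns"
            linked.append((g.gene_id, call))
        links[se_id] = sorted(linked)
    return links
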