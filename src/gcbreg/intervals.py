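"""Genomic interval engine.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` contains position ``p`` iff ``start <= p < end``.
Peak strand is ignored throughout — chromatin accessibility is unstranded.

The module provides the interval primitives the enhancer analyses are
built on: gap-limited stitching (the first step of ROSE super-enhancer
calling), GREAT basal-plus-extension regulatory domains, TAD assignment
by maximal overlap, closest-TSS linkage, and promoter/distal annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "RegulatoryDomain",
    "StitchedRegion",
    "stitch",
    "great_domains",
    "assign_to_tads",
    "closest_tss",
    "annotate_feature",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its TSS; strand orients the basal domain."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class RegulatoryDomain:
    """GREAT-style regulatory domain: a basal window inside an extension."""

    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.extended.chrom == self.basal.chrom
            and self.extended.start <= self.basal.start
            and self.extended.end >= self.basal.end
        ):
            raise ValueError(f"gene {self.gene_id}: basal not contained in extended")


@dataclass
class StitchedRegion:
    """A stitched interval plus the indices of its member inputs."""

    interval: GenomicInterval
    members: list = field(default_factory=list)


def _validate_intervals(intervals: Sequence[GenomicInterval]) -> None:
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            raise TypeError("expected GenomicInterval instances")


def stitch(intervals: Sequence[GenomicInterval], max_gap: int) -> list[StitchedRegion]:
    """Merge intervals connected by chains of gaps <= ``max_gap``.

    Two intervals end up in the same stitched region iff a chain of
    pairwise gaps of at most ``max_gap`` bp connects them (gap between
    ``[a,b)`` and ``[c,d)`` with ``c >= b`` is ``c - b``; overlapping or
    bookended intervals have gap 0).  Output regions are sorted by
    (chrom, start) and each input index appears in exactly one region.
    Idempotent: re-stitching the output intervals yields the same regions.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    _validate_intervals(intervals)
    if not intervals:
        return []

    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
    out: list[StitchedRegion] = []
    cur_chrom = None
    cur_start = cur_end = 0
    cur_members: list[int] = []
    for idx in order:
        iv = intervals[idx]
        if cur_chrom == iv.chrom and iv.start - cur_end <= max_gap:
            cur_end = max(cur_end, iv.end)
            cur_members.append(idx)
        else:
            if cur_members:
                out.append(StitchedRegion(GenomicInterval(cur_chrom, cur_start, cur_end), cur_members))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_members = [idx]
    out.append(StitchedRegion(GenomicInterval(cur_chrom, cur_start, cur_end), cur_members))
    return out


def great_domains(
    genes: Sequence[GeneAnnotation],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """GREAT basal-plus-extension regulatory domains.

    The basal domain spans ``basal_up`` bp upstream and ``basal_down`` bp
    downstream of the TSS (strand-oriented).  The extended domain reaches
    from the basal boundary toward the nearest neighboring gene's basal
    domain in each direction, capped at ``max_ext`` bp and clipped at the
    chromosome start; an extension never shrinks a gene's own basal
    domain, so overlapping basal domains simply coexist.
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)

    basal: dict[str, GenomicInterval] = {}
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - basal_up, g.tss + basal_down
        else:
            s, e = g.tss - basal_down, g.tss + basal_up
        basal[g.gene_id] = GenomicInterval(g.chrom, max(0, s), e)

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: list[RegulatoryDomain] = []
    for g in genes:
        b = basal[g.gene_id]
        others = [basal[h.gene_id] for h in by_chrom[g.chrom] if h.gene_id != g.gene_id]
        # nearest basal boundary on each side; strictly up/downstream of this basal
        up_limits = [o.end for o in others if o.end < b.end]
        down_limits = [o.start for o in others if o.start > b.start]
        ext_start = max(b.start - max_ext, 0, max(up_limits, default=0))
        ext_start = min(ext_start, b.start)  # never shrink the basal domain
        ext_end = min(b.end + max_ext, min(down_limits, default=b.end + max_ext))
        ext_end = max(ext_end, b.end)
        domains.append(RegulatoryDomain(g.gene_id, b, GenomicInterval(g.chrom, ext_start, ext_end)))
    return domains


def assign_to_tads(
    items: Sequence[GenomicInterval] | Sequence[GeneAnnotation],
    tads: Mapping[str, GenomicInterval] | Sequence[tuple[str, GenomicInterval]],
) -> dict[int, Optional[str]]:
    """Map each item to a TAD id, or None.

    Intervals map to the TAD of maximal overlap (>= 1 bp; ties to the
    lexicographically first tad_id); genes map by TSS containment under
    the half-open convention.  Every input index appears in the output.
    """
    tad_items = list(tads.items()) if isinstance(tads, Mapping) else list(tads)
    # non-overlap invariant within chromosome
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for tid, tiv in tad_items:
        by_chrom.setdefault(tiv.chrom, []).append((tid, tiv))
    for chrom, tl in by_chrom.items():
        tl.sort(key=lambda t: t[1].start)
        for (_, a), (_, b) in zip(tl, tl[1:]):
            if a.overlap_length(b) > 0:
                raise ValueError(f"TADs overlap on {chrom}: {a} vs {b}")

    result: dict[int, Optional[str]] = {}
    for i, item in enumerate(items):
        if isinstance(item, GeneAnnotation):
            hit = None
            for tid, tiv in sorted(by_chrom.get(item.chrom, []), key=lambda t: t[0]):
                if tiv.start <= item.tss < tiv.end:
                    hit = tid
                    break
            result[i] = hit
        else:
            best_id, best_len = None, 0
            for tid, tiv in sorted(by_chrom.get(item.chrom, []), key=lambda t: t[0]):
                ov = item.overlap_length(tiv)
                if ov > best_len:
                    best_id, best_len = tid, ov
            result[i] = best_id
    return result


def closest_tss(
    peaks: Sequence[GenomicInterval], genes: Sequence[GeneAnnotation]
) -> list[Optional[tuple[str, int]]]:
    """Per-peak (gene_id, signed distance) of the closest TSS.

    Distance is 0 when the TSS lies inside the peak; otherwise the
    distance from the nearer peak edge to the TSS, negative when the TSS
    is left of the peak.  Equidistant genes resolve to the
    lexicographically smaller gene_id.  Peaks on a gene-less chromosome
    map to None.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[Optional[tuple[str, int]]] = []
    for pk in peaks:
        cands = by_chrom.get(pk.chrom)
        if not cands:
            out.append(None)
            continue
        best: Optional[tuple[int, str, int]] = None  # (abs, gene_id, signed)
        for g in cands:
            if pk.start <= g.tss < pk.end:
                signed = 0
            elif g.tss < pk.start:
                signed = g.tss - pk.start
            else:
                signed = g.tss - (pk.end - 1)
            key = (abs(signed), g.gene_id, signed)
            if best is None or key < best:
                best = key
        out.append((best[1], best[2]))
    return out


def annotate_feature(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    promoter_halfwidth: int = 5000,
) -> list[str]:
    """Label each peak 'promoter' (closest TSS within +/- halfwidth,
    inclusive) or 'distal'."""
    hits = closest_tss(peaks, genes)
    labels = []
    for h in hits:
        if h is not None and abs(h[1]) <= promoter_halfwidth:
            labels.append("promoter")
        else:
            labels.append("distal")
    return labels
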