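"""Plain-text readers and writers: BED3/BED6, TSV tables, GMT gene sets.

BED files are tab-separated without header, 0-based half-open.  Count,
motif, GC, cell and clone tables are TSV with a header row and the
feature id in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .enrichment import GeneSetCollection
from .intervals import GeneAnnotation, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_tads_bed",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "read_gmt",
    "write_json",
]


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(path, intervals: Sequence[GenomicInterval], names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_genes_tsv(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_genes_tsv(path, genes: Sequence[GeneAnnotation]) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_tads_bed(path) -> dict[str, GenomicInterval]:
    tads = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            tad_id = f[3] if len(f) >= 4 else f"tad_{i:03d}"
            tads[tad_id] = GenomicInterval(f[0], int(f[1]), int(f[2]))
    return tads


def write_tads_bed(path, tads: dict[str, GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for tid, iv in tads.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{tid}\n")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_sheet(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def read_gmt(path, universe=None) -> GeneSetCollection:
    sets = {}
    all_genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            genes = {g for g in f[2:] if g}
            sets[f[0]] = genes
            all_genes |= genes
    return GeneSetCollection(sets=sets, universe=set(universe) if universe is not None else all_genes)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
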