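"""Readers and writers for the plain-text formats the pipeline exchanges.

BED3/BED6 for peaks and TADs, BED12 for gene models, TSV for count
matrices and result tables.  All files are tab-separated without headers
(BED) or with a single header row (TSV).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .intervals import GeneModel, GenomicInterval, PeakSet, TADSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_bed12",
    "write_bed12",
    "read_tads",
    "write_tads",
]


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read BED3/BED6 into a :class:`PeakSet` (name col 4, strand col 6)."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
            intervals.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), name, strand)
            )
    return PeakSet(label or path.stem, intervals, provenance=str(path))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for iv in peaks:
            row = [iv.chrom, iv.start, iv.end]
            if iv.name is not None or iv.strand is not None:
                row += [iv.name or ".", 0, iv.strand or "."]
            w.writerow(row)


def read_tads(path: str | Path) -> TADSet:
    return TADSet(read_bed(path).intervals)


def write_tads(tads: TADSet, path: str | Path) -> None:
    write_bed(PeakSet("tads", list(tads)), path)


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks define exons; thickStart unused)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + s, start + s + sz)
                for s, sz in zip(starts, sizes)
            ]
            genes.append(
                GeneModel(name, GenomicInterval(chrom, start, end, name), strand, exons)
            )
    return genes


def write_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in genes:
            b = g.body
            sizes = ",".join(str(e.length) for e in g.exons)
            starts = ",".join(str(e.start - b.start) for e in g.exons)
            w.writerow(
                [
                    b.chrom, b.start, b.end, g.gene_id, 0, g.strand,
                    b.start, b.end, "0", len(g.exons), sizes, starts,
                ]
            )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
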