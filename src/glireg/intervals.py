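"""Genomic interval data model and overlap / proximity / TAD operations.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A 1 bp overlap is the definition of "bound at" /
"enriched at" used by every downstream module; no minimum overlap
fraction or summit logic is applied.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "TADSet",
    "GeneModel",
    "overlaps",
    "intersect_sets",
    "region_gene_distance",
    "assign_tad",
]


class IntervalError(ValueError):
    """Raised for invalid interval geometry or undefined operations."""


@dataclass(frozen=True, order=True, slots=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    name : str, optional
        Identifier (BED column 4).
    strand : str, optional
        ``"+"``, ``"-"`` or ``None`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


@dataclass
class PeakSet:
    """A labelled collection of called peaks from one assay/condition."""

    label: str
    intervals: list[GenomicInterval]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.label,
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            self.provenance,
        )

    def duplicate_coordinates(self) -> list[GenomicInterval]:
        """Duplicated (chrom, start, end) triples — permitted but flagged."""
        seen: set[tuple[str, int, int]] = set()
        dups = []
        for iv in self.intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                dups.append(iv)
            seen.add(key)
        return dups


class TADSet:
    """Topologically associating domains: uniquely named, non-overlapping
    within each chromosome (validated on construction)."""

    def __init__(self, tads: list[GenomicInterval]):
        names = [t.name for t in tads]
        if any(n is None for n in names):
            raise IntervalError("every TAD must be named")
        if len(set(names)) != len(names):
            raise IntervalError("TAD names must be unique")
        by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
        for t in tads:
            by_chrom[t.chrom].append(t)
        for chrom, ts in by_chrom.items():
            ts.sort(key=lambda t: t.start)
            for a, b in zip(ts, ts[1:]):
                if b.start < a.end:
                    raise IntervalError(
                        f"TADs {a.name} and {b.name} overlap on {chrom}"
                    )
        self.tads = sorted(tads, key=lambda t: (t.chrom, t.start))
        self._by_chrom = dict(by_chrom)

    def __len__(self) -> int:
        return len(self.tads)

    def __iter__(self):
        return iter(self.tads)


@dataclass
class GeneModel:
    """A gene body with an ordered exon structure.

    The TSS is ``body.start`` for + strand genes and ``body.end - 1``
    for − strand genes (the last covered base of a half-open interval).
    """

    gene_id: str
    body: GenomicInterval
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise IntervalError(f"gene strand must be +/-, got {self.strand!r}")
        if not self.exons:
            raise IntervalError(f"gene {self.gene_id}: at least one exon required")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.body.chrom:
                raise IntervalError(f"gene {self.gene_id}: exon off-chromosome")
            if e.start < self.body.start or e.end > self.body.end:
                raise IntervalError(f"gene {self.gene_id}: exon outside body")
            if prev_end is not None and e.start < prev_end:
                raise IntervalError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e.end

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, within the body."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.body.chrom, a.end, b.start))
        return out


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise IntervalError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in peaks:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    return trees


def intersect_sets(
    a: PeakSet, b: PeakSet, min_bp: int = 1
) -> list[list[GenomicInterval]]:
    """Map every interval of ``a`` to the intervals of ``b`` it overlaps.

    Returns a list parallel to ``a.intervals``; intervals with no partner
    map to an empty list.  Partner lists are sorted by coordinate so the
    result is independent of the input order of ``b``.
    """
    trees = _build_trees(b)
    out: list[list[GenomicInterval]] = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            out.append([])
            continue
        hits = [
            h.data
            for h in tree.overlap(iv.start, iv.end)
            if min(iv.end, h.data.end) - max(iv.start, h.data.start) >= min_bp
        ]
        hits.sort(key=lambda h: (h.start, h.end, h.name or ""))
        out.append(hits)
    return out


def region_gene_distance(region: GenomicInterval, gene: GeneModel) -> int:
    """Absolute distance (bp) from the region midpoint to the gene TSS.

    Undefined across chromosomes (raises :class:`IntervalError`).
    """
    if region.chrom != gene.body.chrom:
        raise IntervalError(
            f"distance undefined: {region.chrom} vs {gene.body.chrom}"
        )
    return abs(region.midpoint - gene.tss)


def assign_tad(x: GenomicInterval, tads: TADSet) -> str | None:
    """Name of the TAD containing the midpoint of ``x``, or ``None``.

    Containment is half-open, so a midpoint sitting exactly on a TAD's
    end coordinate belongs to the TAD starting there, if any.
    """
    mid = x.midpoint
    for t in tads._by_chrom.get(x.chrom, ()):
        if t.start <= mid < t.end:
            return t.name
    return None
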