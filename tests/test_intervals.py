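"""Interval engine: construction invariants, overlap/linking semantics,
and exact agreement with brute-force all-pairs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glireg.bedio import read_bed, read_bed12, write_bed, write_bed12, write_tads, read_tads
from glireg.intervals import (
    GeneModel,
    GenomicInterval,
    IntervalError,
    PeakSet,
    TADSet,
    assign_tad,
    intersect_sets,
    overlaps,
    region_gene_distance,
)
from conftest import random_intervals


class TestGenomicInterval:
    def test_valid_construction(self):
        iv = GenomicInterval("chr1", 100, 200, "a", "+")
        assert iv.length == 100
        assert iv.midpoint == 150

    @pytest.mark.parametrize(
        "chrom,start,end",
        [("", 0, 10), ("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 20, 10)],
    )
    def test_invalid_rejected(self, chrom, start, end):
        with pytest.raises(IntervalError):
            GenomicInterval(chrom, start, end)


class TestOverlaps:
    def test_simple_overlap(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 150, 250)
        assert overlaps(a, b)
        assert overlaps(a, b, min_bp=50)
        assert not overlaps(a, b, min_bp=51)

    def test_half_open_adjacency(self):
        a = GenomicInterval("chr1", 100, 200)
        b = GenomicInterval("chr1", 200, 300)
        assert not overlaps(a, b)

    def test_different_chromosomes(self):
        assert not overlaps(
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100)
        )

    def test_matches_coordinate_oracle_and_symmetry(self, rng):
        ivs = random_intervals(rng, 2000, span=5000)
        pairs = rng.integers(0, len(ivs), size=(1000, 2))
        for i, j in pairs:
            a, b = ivs[i], ivs[j]
            oracle = a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)
            assert overlaps(a, b) == oracle == overlaps(b, a)


class TestIntersectSets:
    def test_empty_partner(self):
        a = PeakSet("a", [GenomicInterval("chr1", 0, 10)])
        assert intersect_sets(a, PeakSet("b", [])) == [[]]

    def test_chromosome_separation(self):
        a = PeakSet("a", [GenomicInterval("chr1", 0, 10)])
        b = PeakSet(
            "b",
            [
                GenomicInterval("chr1", 5, 8),
                GenomicInterval("chr1", 9, 20),
                GenomicInterval("chr2", 0, 10),
            ],
        )
        (hits,) = intersect_sets(a, b)
        assert [(h.start, h.end) for h in hits] == [(5, 8), (9, 20)]

    def test_matches_brute_force_and_symmetric_counts(self, rng):
        A = PeakSet("A", random_intervals(rng, 500, span=50_000))
        B = PeakSet("B", random_intervals(rng, 500, span=50_000))
        got = intersect_sets(A, B)
        expected = [[b for b in B if overlaps(a, b)] for a in A]
        for g, e in zip(got, expected):
            assert sorted(g, key=lambda v: (v.start, v.end, v.name)) == sorted(
                e, key=lambda v: (v.start, v.end, v.name)
            )
        # unordered pair multiset identical with roles swapped
        n_ab = sum(len(h) for h in got)
        n_ba = sum(len(h) for h in intersect_sets(B, A))
        assert n_ab == n_ba

    def test_order_invariance(self, rng):
        A = PeakSet("A", random_intervals(rng, 100, span=5000))
        B = PeakSet("B", random_intervals(rng, 100, span=5000))
        perm = list(rng.permutation(len(B.intervals)))
        B_shuffled = PeakSet("B", [B.intervals[i] for i in perm])
        assert intersect_sets(A, B) == intersect_sets(A, B_shuffled)


def _gene(chrom="chr1", start=1000, end=9000, strand="+", exons=None):
    exons = exons or [(start, start + 500), (end - 500, end)]
    return GeneModel(
        "g1",
        GenomicInterval(chrom, start, end),
        strand,
        [GenomicInterval(chrom, s, e) for s, e in exons],
    )


class TestGeneModel:
    def test_tss_by_strand(self):
        assert _gene(strand="+").tss == 1000
        assert _gene(strand="-").tss == 8999

    def test_exon_outside_body_rejected(self):
        with pytest.raises(IntervalError):
            _gene(exons=[(500, 1500)])

    def test_overlapping_exons_rejected(self):
        with pytest.raises(IntervalError):
            _gene(exons=[(1000, 2000), (1500, 2500)])

    def test_introns(self):
        g = _gene(exons=[(1000, 2000), (3000, 4000), (8000, 9000)])
        assert [(i.start, i.end) for i in g.introns()] == [(2000, 3000), (4000, 8000)]


class TestRegionGeneDistance:
    def test_midpoint_on_tss(self):
        g = _gene(start=1500, end=9000, exons=[(1500, 2000), (8500, 9000)])
        assert region_gene_distance(GenomicInterval("chr1", 1000, 2000), g) == 0

    def test_arithmetic(self):
        g = _gene(start=100_300, end=200_000, exons=[(100_300, 101_000), (199_000, 200_000)])
        assert region_gene_distance(GenomicInterval("chr1", 0, 200), g) == 100_200

    def test_cross_chromosome_undefined(self):
        with pytest.raises(IntervalError):
            region_gene_distance(GenomicInterval("chr2", 0, 200), _gene())

    def test_random_recomputation(self, rng):
        for _ in range(100):
            start = int(rng.integers(0, 10_000))
            length = int(rng.integers(2, 2000))
            region = GenomicInterval("chr1", start, start + length)
            gs = int(rng.integers(0, 50_000))
            g = _gene(start=gs, end=gs + 5000, exons=[(gs, gs + 100), (gs + 4900, gs + 5000)])
            assert region_gene_distance(region, g) == abs(
                (start + start + length) // 2 - gs
            )


class TestAssignTad:
    tads = TADSet(
        [
            GenomicInterval("chr1", 0, 1000, "t1"),
            GenomicInterval("chr1", 1000, 2000, "t2"),
            GenomicInterval("chr2", 0, 500, "t3"),
        ]
    )

    def test_inside(self):
        assert assign_tad(GenomicInterval("chr1", 100, 300), self.tads) == "t1"

    def test_outside(self):
        assert assign_tad(GenomicInterval("chr1", 2500, 2600), self.tads) is None
        assert assign_tad(GenomicInterval("chr3", 0, 100), self.tads) is None

    def test_boundary_belongs_to_starting_tad(self):
        # midpoint exactly 1000 = end of t1 = start of t2
        assert assign_tad(GenomicInterval("chr1", 900, 1100), self.tads) == "t2"

    def test_overlapping_tads_rejected(self):
        with pytest.raises(IntervalError):
            TADSet(
                [
                    GenomicInterval("chr1", 0, 1000, "a"),
                    GenomicInterval("chr1", 500, 1500, "b"),
                ]
            )

    def test_duplicate_names_rejected(self):
        with pytest.raises(IntervalError):
            TADSet(
                [
                    GenomicInterval("chr1", 0, 10, "a"),
                    GenomicInterval("chr1", 20, 30, "a"),
                ]
            )


@given(
    start=st.integers(0, 10_000),
    length=st.integers(1, 5000),
    shift=st.integers(-6000, 6000),
    length2=st.integers(1, 5000),
)
@settings(max_examples=200, derandomize=True)
def test_overlap_symmetry_property(start, length, shift, length2):
    a = GenomicInterval("chr1", start, start + length)
    s2 = max(0, start + shift)
    b = GenomicInterval("chr1", s2, s2 + length2)
    assert overlaps(a, b) == overlaps(b, a)


class TestBedIO:
    def test_bed_roundtrip(self, tmp_path, rng):
        ps = PeakSet("x", random_intervals(rng, 50))
        path = tmp_path / "x.bed"
        write_bed(ps, path)
        back = read_bed(path, "x")
        assert [(i.chrom, i.start, i.end, i.name) for i in back] == [
            (i.chrom, i.start, i.end, i.name) for i in ps
        ]

    def test_bed12_roundtrip(self, tmp_path):
        g = _gene(exons=[(1000, 1400), (2000, 2600), (8500, 9000)])
        path = tmp_path / "g.bed12"
        write_bed12([g], path)
        (back,) = read_bed12(path)
        assert back.gene_id == g.gene_id
        assert (back.body.start, back.body.end) == (g.body.start, g.body.end)
        assert [(e.start, e.end) for e in back.exons] == [
            (e.start, e.end) for e in g.exons
        ]

    def test_tads_roundtrip(self, tmp_path):
        tads = TADSet(
            [GenomicInterval("chr1", 0, 100, "a"), GenomicInterval("chr1", 100, 300, "b")]
        )
        path = tmp_path / "t.bed"
        write_tads(tads, path)
        back = read_tads(path)
        assert [(t.name, t.start, t.end) for t in back] == [
            ("a", 0, 100), ("b", 100, 300)
        ]

    def test_duplicates_flagged(self):
        ps = PeakSet(
            "d",
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 0, 10)],
        )
        assert len(ps.duplicate_coordinates()) == 1
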