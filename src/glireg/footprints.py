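"""Footprint motif-containment fractions and the between-condition
enrichment test.

A footprint "contains" a motif hit when the hit interval lies entirely
within the footprint (strict containment, not mere overlap).  The
enrichment ratio is the ratio of containment fractions between two
conditions, and the difference is tested with a two-sided Fisher exact
test on the 2x2 table (with motif / without motif) x (condition A / B).

The Fisher p-value is computed in exact integer arithmetic: for fixed
margins every table probability is an integer numerator over a common
denominator, so the probability-mass two-sided rule (sum all tables at
most as probable as the observed one) involves no floating-point tie
ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .intervals import PeakSet, intersect_sets

__all__ = [
    "ContingencyTable",
    "footprint_motif_fraction",
    "enrichment_ratio",
    "fisher_exact",
    "footprint_enrichment",
]


class UndefinedValueError(ValueError):
    """A fraction or ratio is undefined (empty denominator)."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = conditions (A, B), columns = (with, without motif).

    a = A with motif, b = A without, c = B with, d = B without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def footprint_motif_fraction(
    footprints: PeakSet, motif_hits: PeakSet
) -> tuple[float, int, int]:
    """Fraction of footprints fully containing at least one motif hit.

    Returns ``(fraction, count_with, count_total)``.  A hit overhanging
    a footprint edge does not count.
    """
    total = len(footprints)
    if total == 0:
        raise UndefinedValueError("no footprints: fraction undefined")
    with_motif = 0
    for fp, hits in zip(footprints, intersect_sets(footprints, motif_hits)):
        if any(h.start >= fp.start and h.end <= fp.end for h in hits):
            with_motif += 1
    return with_motif / total, with_motif, total


def enrichment_ratio(frac_a: float, frac_b: float) -> float:
    """frac_a / frac_b; undefined (raises) when frac_b is 0."""
    if frac_b == 0:
        raise UndefinedValueError("enrichment ratio undefined: frac_b is 0")
    return frac_a / frac_b


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the probability-mass method.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.
    Computed exactly on integers, then floated.  A zero row or column
    margin makes the table degenerate; p is reported as 1.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # numerators C(r1, a) * C(r2, c1 - a); common denominator C(n, c1)
    nums = [comb(r1, a) * comb(r2, c1 - a) for a in range(lo, hi + 1)]
    observed = nums[t.a - lo]
    p = sum(v for v in nums if v <= observed) / comb(n, c1)
    return min(p, 1.0)


def footprint_enrichment(
    footprints_a: PeakSet,
    footprints_b: PeakSet,
    motif_hits: PeakSet,
    restrict: PeakSet | None = None,
) -> dict:
    """Full per-motif enrichment summary between two conditions.

    ``restrict`` optionally limits each condition's footprints to those
    overlapping a region set (e.g. regions with pre-HH-only GLI binding)
    before fractions are computed.
    """
    if restrict is not None:
        def _restrict(ps: PeakSet) -> PeakSet:
            hits = intersect_sets(ps, restrict)
            return PeakSet(ps.label, [iv for iv, h in zip(ps, hits) if h])

        footprints_a = _restrict(footprints_a)
        footprints_b = _restrict(footprints_b)

    frac_a, with_a, n_a = footprint_motif_fraction(footprints_a, motif_hits)
    frac_b, with_b, n_b = footprint_motif_fraction(footprints_b, motif_hits)
    table = ContingencyTable(with_a, n_a - with_a, with_b, n_b - with_b)
    try:
        ratio = enrichment_ratio(frac_a, frac_b)
    except UndefinedValueError:
        ratio = None
    return {
        "fraction_a": frac_a,
        "fraction_b": frac_b,
        "n_a": n_a,
        "n_b": n_b,
        "with_motif_a": with_a,
        "with_motif_b": with_b,
        "enrichment_ratio": ratio,
        "contingency": [table.a, table.b, table.c, table.d],
        "p_value": fisher_exact(table),
    }
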