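"""Chromatin-state and repression-competence classification.

GLI binding regions (GBRs) are flagged against the assay peak sets
(GLI3 pre/post HH, ATAC, H3K4me1/2, H3K27ac, H3K27me3) by 1 bp overlap.
A region is a *poised enhancer* when it is ATAC-accessible and carries
H3K4me1 or H3K4me2.  A GBR is *HH-responsive* when its H3K27ac is
significantly reduced (FDR < alpha, reduction sign) in the constitutively
repressed condition.  Genes are classified into repression-competence
classes from promoter H3K27me3/H3K27ac and GLI3 binding.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from .diffenrich import call_differential
from .intervals import GeneModel, GenomicInterval, PeakSet, intersect_sets

__all__ = [
    "PROMOTER_WINDOW",
    "CompetenceClass",
    "flag_overlaps",
    "annotate_regions",
    "classify_poised",
    "call_hh_responsive",
    "binding_overlap_summary",
    "promoter_interval",
    "classify_gene_competence",
    "gene_competence_table",
]

#: promoter = TSS +/- 2 kb for promoter-mark flags
PROMOTER_WINDOW = 2000


class CompetenceClass(str, Enum):
    COMPETENT = "competent"
    BIVALENT = "bivalent"
    PRC2_REPRESSED = "prc2_repressed"
    UNCLASSIFIED = "unclassified"


def flag_overlaps(regions: PeakSet, other: PeakSet, min_bp: int = 1) -> list[bool]:
    """Per-region boolean: overlaps >=1 interval of ``other`` by ``min_bp``."""
    return [len(hits) > 0 for hits in intersect_sets(regions, other, min_bp)]


def annotate_regions(
    gbrs: PeakSet, peak_sets: dict[str, PeakSet]
) -> pd.DataFrame:
    """Boolean flag table for GBRs against each named assay peak set.

    Returns a DataFrame indexed by region name (or ``region_<i>`` when
    unnamed) with one boolean column per entry of ``peak_sets`` plus a
    derived ``poised`` column when ``atac`` and ``k4me1``/``k4me2``
    columns are all present.
    """
    ids = [iv.name or f"region_{i}" for i, iv in enumerate(gbrs)]
    data = {key: flag_overlaps(gbrs, ps) for key, ps in sorted(peak_sets.items())}
    ann = pd.DataFrame(data, index=pd.Index(ids, name="region_id"))
    if {"atac", "k4me1", "k4me2"} <= set(ann.columns):
        ann["poised"] = ann["atac"] & (ann["k4me1"] | ann["k4me2"])
    return ann


def classify_poised(atac: bool, k4me1: bool, k4me2: bool) -> bool:
    """Poised enhancer: accessible and carrying H3K4me1 or H3K4me2."""
    return bool(atac and (k4me1 or k4me2))


def call_hh_responsive(
    gbrs: PeakSet,
    k27ac_diff: pd.DataFrame,
    alpha: float = 0.05,
    reduced_direction: str = "down",
) -> list[str]:
    """GBRs whose H3K27ac is significantly reduced under constitutive
    repression (FDR < alpha with the reduction sign).

    ``k27ac_diff`` is a diff table indexed by region id for the
    repressed-vs-active contrast (log2fc = repressed − active, so
    reduction is ``"down"``).  Every GBR must appear in the table.
    """
    ids = [iv.name for iv in gbrs]
    if any(i is None for i in ids):
        raise ValueError("every GBR needs a name matching the diff table")
    missing = [i for i in ids if i not in k27ac_diff.index]
    if missing:
        raise ValueError(f"GBRs missing from diff table: {missing[:5]}...")
    flagged = set(
        call_differential(k27ac_diff.loc[ids], alpha, direction_filter=reduced_direction)
    )
    return [i for i in ids if i in flagged]


def binding_overlap_summary(
    pre: PeakSet,
    post: PeakSet,
    subset: PeakSet | None = None,
) -> dict:
    """Shared / exclusive binding counts between two conditions.

    ``shared`` counts post-condition regions overlapping (1 bp) at least
    one pre-condition region; ``pre_only``/``post_only`` count regions
    with no partner.  ``pct_post_bound_pre`` = shared / |post| as a
    percentage rounded to 0.1.  ``subset`` restricts both sets to
    regions overlapping it (e.g. HH-responsive regions only).
    """
    if subset is not None:
        pre = PeakSet(pre.label, [iv for iv, ok in zip(pre, flag_overlaps(pre, subset)) if ok])
        post = PeakSet(post.label, [iv for iv, ok in zip(post, flag_overlaps(post, subset)) if ok])
    if len(post) == 0:
        raise ValueError("percentage undefined for an empty post set")
    post_hit = flag_overlaps(post, pre)
    pre_hit = flag_overlaps(pre, post)
    shared = sum(post_hit)
    return {
        "shared": shared,
        "pre_only": len(pre) - sum(pre_hit),
        "post_only": len(post) - shared,
        "pct_post_bound_pre": round(100.0 * shared / len(post), 1),
    }


def promoter_interval(gene: GeneModel, window: int = PROMOTER_WINDOW) -> GenomicInterval:
    """TSS +/- ``window`` bp, clipped at the chromosome origin."""
    tss = gene.tss
    return GenomicInterval(
        gene.body.chrom, max(0, tss - window), tss + window, gene.gene_id
    )


def classify_gene_competence(
    gli3_bound: bool, promoter_k27me3: bool, promoter_k27ac: bool
) -> CompetenceClass:
    """Repression-competence class from three promoter/binding booleans.

    competent: GLI3-bound without promoter H3K27me3 (de-repressible);
    bivalent: promoter carries both H3K27me3 and H3K27ac (population
    heterogeneity, the marks being mutually exclusive on one tail);
    prc2_repressed: H3K27me3 without H3K27ac (likely not competent);
    precedence competent > bivalent > prc2_repressed.
    """
    if gli3_bound and not promoter_k27me3:
        return CompetenceClass.COMPETENT
    if promoter_k27me3 and promoter_k27ac:
        return CompetenceClass.BIVALENT
    if promoter_k27me3 and not promoter_k27ac:
        return CompetenceClass.PRC2_REPRESSED
    return CompetenceClass.UNCLASSIFIED


def gene_competence_table(
    genes: list[GeneModel],
    gli3_peaks: PeakSet,
    k27me3_peaks: PeakSet,
    k27ac_peaks: PeakSet,
    window: int = PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Per-gene competence classification from peak sets.

    GLI3 binding is evaluated over the gene body; H3K27me3/H3K27ac over
    the TSS +/- window promoter.
    """
    bodies = PeakSet("bodies", [g.body for g in genes])
    promoters = PeakSet("promoters", [promoter_interval(g, window) for g in genes])
    bound = flag_overlaps(bodies, gli3_peaks)
    me3 = flag_overlaps(promoters, k27me3_peaks)
    ac = flag_overlaps(promoters, k27ac_peaks)
    rows = {
        g.gene_id: {
            "gli3_bound": b,
            "promoter_k27me3": m,
            "promoter_k27ac": a,
            "class": classify_gene_competence(b, m, a).value,
        }
        for g, b, m, a in zip(genes, bound, me3, ac)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df
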