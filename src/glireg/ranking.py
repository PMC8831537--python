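"""Weighted GLI target-gene prediction and ranking.

HH-responsive GLI binding regions (GBRs) carrying poised-enhancer
modifications get a higher weight than bare responsive GBRs; genes
significantly downregulated under constitutive repression get a higher
weight when their promoter carries the active mark H3K4me3.  Weighted
GBRs and weighted genes are linked when they lie within ``max_distance``
(default 500 kb, midpoint-to-TSS) and share a TAD; a gene's score is the
sum over its links of

    gbr_weight * gene_weight * decay(distance)

so a gene with several nearby poised responsive GBRs outranks one with a
single distal bare GBR.  The numeric weights and the decay form are
configurable; only the orderings (poised > bare, marked > unmarked,
nearer > farther, more links > fewer) are fixed by the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    TADSet,
    assign_tad,
    region_gene_distance,
)

__all__ = [
    "ScoringConfig",
    "TargetLink",
    "TargetScore",
    "weight_gbrs",
    "weight_genes",
    "link_and_score",
    "select_high_confidence",
    "scores_to_frame",
]

DECAY_FAMILIES = ("linear", "quadratic", "exponential")


@dataclass
class ScoringConfig:
    """Weights, linking constraints and distance decay for target scoring.

    Decay families (all 1 at d=0, strictly decreasing on [0, max_distance),
    and 0 at d >= max_distance):

    - ``linear``: 1 − d/max_distance
    - ``quadratic``: (1 − d/max_distance)²
    - ``exponential``: exp(−d/decay_scale), truncated at max_distance

    ``high_confidence_rule`` is ``{"top_k": k}`` or ``{"min_score": s}``.
    """

    w_gbr_poised: float = 2.0
    w_gbr_base: float = 1.0
    w_gene_promoter_mark: float = 2.0
    w_gene_base: float = 1.0
    max_distance: int = 500_000
    require_same_tad: bool = True
    decay: str = "linear"
    decay_scale: float = 100_000.0
    high_confidence_rule: dict = field(default_factory=lambda: {"top_k": 74})

    def __post_init__(self) -> None:
        if not (self.w_gbr_poised > self.w_gbr_base > 0):
            raise ValueError("require w_gbr_poised > w_gbr_base > 0")
        if not (self.w_gene_promoter_mark > self.w_gene_base > 0):
            raise ValueError("require w_gene_promoter_mark > w_gene_base > 0")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.decay not in DECAY_FAMILIES:
            raise ValueError(f"unknown decay family {self.decay!r}")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be positive")

    def decay_value(self, distance: float) -> float:
        """Decay weight in [0, 1]; 0 at or beyond max_distance."""
        if distance < 0:
            raise ValueError("distance must be non-negative")
        if distance >= self.max_distance:
            return 0.0
        frac = distance / self.max_distance
        if self.decay == "linear":
            return 1.0 - frac
        if self.decay == "quadratic":
            return (1.0 - frac) ** 2
        return math.exp(-distance / self.decay_scale)


@dataclass(frozen=True)
class TargetLink:
    region_id: str
    distance: int
    gbr_weight: float
    decay: float


@dataclass
class TargetScore:
    gene_id: str
    score: float
    links: list[TargetLink]
    rank: int = 0


def weight_gbrs(
    responsive_ids: list[str],
    poised_flags: dict[str, bool],
    cfg: ScoringConfig,
) -> dict[str, float]:
    """Weight per responsive GBR; non-responsive regions are excluded.

    Poised responsive GBRs get ``w_gbr_poised``, bare ones ``w_gbr_base``.
    Every responsive id must have a poised flag.
    """
    missing = [r for r in responsive_ids if r not in poised_flags]
    if missing:
        raise ValueError(f"responsive regions without a poised flag: {missing[:5]}")
    return {
        r: cfg.w_gbr_poised if poised_flags[r] else cfg.w_gbr_base
        for r in responsive_ids
    }


def weight_genes(
    de_table: pd.DataFrame,
    promoter_mark_flags: dict[str, bool],
    cfg: ScoringConfig,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Weight per significantly downregulated gene.

    ``de_table`` needs columns ``gene_id``, ``log2fc``, ``fdr``; only rows
    with fdr < alpha and log2fc < 0 (down in the repressed condition)
    enter.  Genes whose promoter overlaps an H3K4me3 peak (per
    ``promoter_mark_flags``) get ``w_gene_promoter_mark``, others
    ``w_gene_base``.
    """
    keep = de_table[(de_table["fdr"] < alpha) & (de_table["log2fc"] < 0)]
    return {
        g: cfg.w_gene_promoter_mark
        if promoter_mark_flags.get(g, False)
        else cfg.w_gene_base
        for g in keep["gene_id"]
    }


def link_and_score(
    weighted_gbrs: dict[str, float],
    weighted_genes: dict[str, float],
    regions: PeakSet,
    genes: list[GeneModel],
    tads: TADSet | None,
    cfg: ScoringConfig,
) -> list[TargetScore]:
    """Link weighted GBRs to weighted genes and rank by summed score.

    A link exists iff the region midpoint lies within ``max_distance`` of
    the gene TSS on the same chromosome and, when ``require_same_tad``,
    both midpoints fall in the same (non-None) TAD.  Genes with no link
    are omitted.  Ties rank lexicographically by gene_id.
    """
    region_by_id = {iv.name: iv for iv in regions if iv.name in weighted_gbrs}
    gene_by_id = {g.gene_id: g for g in genes if g.gene_id in weighted_genes}

    region_tad: dict[str, str | None] = {}
    if cfg.require_same_tad:
        if tads is None:
            raise ValueError("require_same_tad=True needs a TADSet")
        for rid, iv in region_by_id.items():
            region_tad[rid] = assign_tad(iv, tads)

    scores: list[TargetScore] = []
    for gid in sorted(gene_by_id):
        gene = gene_by_id[gid]
        gw = weighted_genes[gid]
        if cfg.require_same_tad:
            gene_tad = assign_tad(gene.body, tads)
            if gene_tad is None:
                continue
        links = []
        for rid in sorted(region_by_id):
            iv = region_by_id[rid]
            if iv.chrom != gene.body.chrom:
                continue
            d = region_gene_distance(iv, gene)
            if d > cfg.max_distance:
                continue
            if cfg.require_same_tad and region_tad[rid] != gene_tad:
                continue
            links.append(TargetLink(rid, d, weighted_gbrs[rid], cfg.decay_value(d)))
        if not links:
            continue
        score = sum(l.gbr_weight * gw * l.decay for l in links)
        scores.append(TargetScore(gid, score, links))

    scores.sort(key=lambda s: (-s.score, s.gene_id))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def select_high_confidence(scores: list[TargetScore], cfg: ScoringConfig) -> list[str]:
    """High-confidence gene list by ``top_k`` or ``min_score`` rule."""
    rule = cfg.high_confidence_rule
    ordered = sorted(scores, key=lambda s: (-s.score, s.gene_id))
    if "top_k" in rule:
        k = rule["top_k"]
        if k <= 0:
            raise ValueError("top_k must be positive")
        return [s.gene_id for s in ordered[:k]]
    if "min_score" in rule:
        thr = rule["min_score"]
        if thr < 0:
            raise ValueError("min_score must be non-negative")
        return [s.gene_id for s in ordered if s.score >= thr]
    raise ValueError("high_confidence_rule needs top_k or min_score")


def scores_to_frame(scores: list[TargetScore]) -> pd.DataFrame:
    """Ranked table: rank, gene_id, score, n_links, best_distance, links."""
    rows = [
        {
            "rank": s.rank,
            "gene_id": s.gene_id,
            "score": round(s.score, 6),
            "n_links": len(s.links),
            "best_distance": min(l.distance for l in s.links),
            "links": ";".join(
                f"{l.region_id},{l.distance},{l.gbr_weight:g},{l.decay:.6g}"
                for l in sorted(s.links, key=lambda l: l.distance)
            ),
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows, columns=["rank", "gene_id", "score", "n_links", "best_distance", "links"]
    )
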