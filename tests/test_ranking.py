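"""Weighted target scoring: weight assignment, linking constraints,
score arithmetic, ordering properties and monotonicity."""

import numpy as np
import pandas as pd
import pytest

from glireg.intervals import GeneModel, GenomicInterval, PeakSet, TADSet
from glireg.ranking import (
    ScoringConfig,
    link_and_score,
    scores_to_frame,
    select_high_confidence,
    weight_gbrs,
    weight_genes,
)


def make_gene(gid, chrom, tss, length=10_000):
    body = GenomicInterval(chrom, tss, tss + length, gid)
    return GeneModel(
        gid, body, "+",
        [GenomicInterval(chrom, tss, tss + 500),
         GenomicInterval(chrom, tss + length - 500, tss + length)],
    )


def region(rid, chrom, mid, width=200):
    return GenomicInterval(chrom, mid - width // 2, mid + width // 2, rid)


ONE_TAD = TADSet([GenomicInterval("chr1", 0, 10_000_000, "t1")])


class TestWeightGbrs:
    cfg = ScoringConfig()

    def test_poised_gets_higher_weight(self):
        w = weight_gbrs(["r1", "r2"], {"r1": True, "r2": False}, self.cfg)
        assert w == {"r1": 2.0, "r2": 1.0}
        assert w["r1"] > w["r2"]

    def test_non_responsive_excluded(self):
        w = weight_gbrs(["r1"], {"r1": True, "r3": True}, self.cfg)
        assert "r3" not in w

    def test_missing_flag_rejected(self):
        with pytest.raises(ValueError):
            weight_gbrs(["r1", "r2"], {"r1": True}, self.cfg)


class TestWeightGenes:
    cfg = ScoringConfig()
    table = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "log2fc": [-1.0, -1.0, 1.0, -1.0],
            "fdr": [0.01, 0.01, 0.01, 0.2],
        }
    )

    def test_marked_vs_unmarked(self):
        w = weight_genes(self.table, {"g1": True, "g2": False}, self.cfg)
        assert w["g1"] == 2.0 and w["g2"] == 1.0

    def test_upregulated_excluded(self):
        w = weight_genes(self.table, {}, self.cfg)
        assert "g3" not in w

    def test_non_significant_excluded(self):
        w = weight_genes(self.table, {}, self.cfg)
        assert "g4" not in w


class TestLinkAndScore:
    def test_score_arithmetic_at_zero_distance(self):
        gene = make_gene("g1", "chr1", 500_000)
        gbr = region("r1", "chr1", 500_000)  # midpoint exactly on the TSS
        scores = link_and_score(
            {"r1": 2.0}, {"g1": 2.0}, PeakSet("p", [gbr]), [gene], ONE_TAD,
            ScoringConfig(),
        )
        assert len(scores) == 1
        assert scores[0].score == pytest.approx(4.0)  # 2 * 2 * decay(0)=1

    def test_beyond_max_distance_no_link(self):
        gene = make_gene("g1", "chr1", 100_000)
        gbr = region("r1", "chr1", 700_000)  # 600 kb away
        scores = link_and_score(
            {"r1": 2.0}, {"g1": 2.0}, PeakSet("p", [gbr]), [gene], ONE_TAD,
            ScoringConfig(),
        )
        assert scores == []

    def test_different_tad_no_link(self):
        tads = TADSet(
            [GenomicInterval("chr1", 0, 300_000, "t1"),
             GenomicInterval("chr1", 300_000, 900_000, "t2")]
        )
        gene = make_gene("g1", "chr1", 100_000)
        gbr = region("r1", "chr1", 400_000)  # 300 kb away but across boundary
        cfg = ScoringConfig()
        assert link_and_score({"r1": 2.0}, {"g1": 2.0}, PeakSet("p", [gbr]), [gene], tads, cfg) == []
        cfg_no_tad = ScoringConfig(require_same_tad=False)
        got = link_and_score({"r1": 2.0}, {"g1": 2.0}, PeakSet("p", [gbr]), [gene], None, cfg_no_tad)
        assert len(got) == 1

    def test_gene_outside_any_tad_unlinked(self):
        tads = TADSet([GenomicInterval("chr1", 0, 50_000, "t1")])
        gene = make_gene("g1", "chr1", 100_000)
        gbr = region("r1", "chr1", 110_000)
        assert link_and_score({"r1": 1.0}, {"g1": 1.0}, PeakSet("p", [gbr]), [gene], tads, ScoringConfig()) == []


class TestSelectHighConfidence:
    def _scores(self):
        gene = make_gene("g1", "chr1", 100)
        cfg = ScoringConfig()
        from glireg.ranking import TargetScore, TargetLink

        return [
            TargetScore("g1", 4.0, [TargetLink("r", 0, 2, 1.0)], 1),
            TargetScore("g2", 4.0, [TargetLink("r", 0, 2, 1.0)], 2),
            TargetScore("g3", 1.0, [TargetLink("r", 0, 1, 0.5)], 3),
        ]

    def test_top_k_with_lexicographic_ties(self):
        cfg = ScoringConfig(high_confidence_rule={"top_k": 2})
        assert select_high_confidence(self._scores(), cfg) == ["g1", "g2"]

    def test_min_score(self):
        cfg = ScoringConfig(high_confidence_rule={"min_score": 3})
        assert select_high_confidence(self._scores(), cfg) == ["g1", "g2"]

    def test_top_k_larger_than_list(self):
        cfg = ScoringConfig(high_confidence_rule={"top_k": 10})
        assert select_high_confidence(self._scores(), cfg) == ["g1", "g2", "g3"]

    def test_invalid_rules(self):
        with pytest.raises(ValueError):
            select_high_confidence([], ScoringConfig(high_confidence_rule={"top_k": 0}))
        with pytest.raises(ValueError):
            select_high_confidence([], ScoringConfig(high_confidence_rule={"min_score": -1}))


def random_config(rng):
    wb = float(rng.uniform(0.2, 3))
    wp = wb * float(rng.uniform(1.05, 4))
    gb = float(rng.uniform(0.2, 3))
    gp = gb * float(rng.uniform(1.05, 4))
    return ScoringConfig(
        w_gbr_poised=wp, w_gbr_base=wb,
        w_gene_promoter_mark=gp, w_gene_base=gb,
        max_distance=int(rng.integers(200_000, 900_000)),
        decay=str(rng.choice(["linear", "quadratic", "exponential"])),
        decay_scale=float(rng.uniform(30_000, 400_000)),
    )


class TestOrderingProperties:
    """The model's qualitative orderings hold for every valid config."""

    def test_orderings_for_random_configs(self, rng):
        for _ in range(100):
            cfg = random_config(rng)
            d_near = int(rng.integers(0, cfg.max_distance // 2))
            d_far = int(rng.integers(d_near + 1, cfg.max_distance))
            g_near = make_gene("g_near", "chr1", 2_000_000)
            g_far = make_gene("g_far", "chr1", 4_000_000)
            g_poised = make_gene("g_poised", "chr1", 6_000_000)
            g_bare = make_gene("g_bare", "chr1", 8_000_000)
            g_two = make_gene("g_two", "chr2", 2_000_000)
            g_one = make_gene("g_one", "chr2", 4_000_000)
            genes = [g_near, g_far, g_poised, g_bare, g_two, g_one]
            regions = PeakSet("p", [
                region("r_near", "chr1", 2_000_000 + d_near),
                region("r_far", "chr1", 4_000_000 + d_far),
                region("r_poised", "chr1", 6_000_000 + d_near),
                region("r_bare", "chr1", 8_000_000 + d_near),
                region("r_two_a", "chr2", 2_000_000 + d_near),
                region("r_two_b", "chr2", 2_000_000 + d_near),
                region("r_one", "chr2", 4_000_000 + d_near),
            ])
            tads = TADSet([
                GenomicInterval("chr1", 0, 10_000_000, "t1"),
                GenomicInterval("chr2", 0, 10_000_000, "t2"),
            ])
            gbr_w = weight_gbrs(
                [iv.name for iv in regions],
                {"r_near": False, "r_far": False,
                 "r_poised": True, "r_bare": False,
                 "r_two_a": False, "r_two_b": False, "r_one": False},
                cfg,
            )
            gene_w = {g.gene_id: cfg.w_gene_base for g in genes}
            scores = {s.gene_id: s.score
                      for s in link_and_score(gbr_w, gene_w, regions, genes, tads, cfg)}
            assert scores["g_near"] > scores["g_far"]      # nearer outranks farther
            assert scores["g_poised"] > scores["g_bare"]   # poised outranks bare
            assert scores["g_two"] > scores["g_one"]       # more GBRs outrank fewer


class TestMonotonicity:
    def test_adding_upgrading_and_nearing_links(self, rng):
        for _ in range(30):
            cfg = random_config(rng)
            tss = 3_000_000
            gene = make_gene("g", "chr1", tss)
            d1 = int(rng.integers(0, cfg.max_distance - 1))
            d2 = int(rng.integers(0, cfg.max_distance - 1))
            base_regions = [region("r1", "chr1", tss + d1)]
            tads = TADSet([GenomicInterval("chr1", 0, 10_000_000, "t")])

            def score(regs, flags):
                w = weight_gbrs([r.name for r in regs], flags, cfg)
                got = link_and_score(w, {"g": 1.0}, PeakSet("p", regs), [gene], tads, cfg)
                return got[0].score if got else 0.0

            s_base = score(base_regions, {"r1": False})
            # adding a link never decreases the score
            s_added = score(base_regions + [region("r2", "chr1", tss + d2)],
                            {"r1": False, "r2": False})
            assert s_added >= s_base - 1e-12
            # upgrading to poised never decreases
            assert score(base_regions, {"r1": True}) >= s_base - 1e-12
            # moving the link closer never decreases
            d_closer = int(rng.integers(0, d1 + 1))
            assert score([region("r1", "chr1", tss + d_closer)], {"r1": False}) >= s_base - 1e-12


class TestDeterminism:
    def test_permutation_invariance(self, rng):
        genes = [make_gene(f"g{i}", "chr1", 200_000 * (i + 1)) for i in range(10)]
        regions = [region(f"r{i}", "chr1", int(rng.integers(100_000, 2_500_000)))
                   for i in range(30)]
        tads = TADSet([GenomicInterval("chr1", 0, 10_000_000, "t")])
        cfg = ScoringConfig()
        flags = {r.name: bool(rng.random() < 0.5) for r in regions}
        gw = {g.gene_id: 1.0 for g in genes}

        def run(region_order, gene_order):
            w = weight_gbrs([r.name for r in region_order], flags, cfg)
            return scores_to_frame(
                link_and_score(w, gw, PeakSet("p", region_order), gene_order, tads, cfg)
            )

        ref = run(regions, genes)
        perm_r = [regions[i] for i in rng.permutation(len(regions))]
        perm_g = [genes[i] for i in rng.permutation(len(genes))]
        pd.testing.assert_frame_equal(ref, run(perm_r, perm_g))


class TestScoringConfigValidation:
    def test_weight_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScoringConfig(w_gbr_poised=1.0, w_gbr_base=2.0)
        with pytest.raises(ValueError):
            ScoringConfig(w_gene_promoter_mark=1.0, w_gene_base=1.0)

    def test_decay_envelope(self):
        for decay in ("linear", "quadratic", "exponential"):
            cfg = ScoringConfig(decay=decay)
            assert cfg.decay_value(0) == 1.0
            assert cfg.decay_value(cfg.max_distance) == 0.0
            assert cfg.decay_value(cfg.max_distance + 1) == 0.0
            ds = np.linspace(0, cfg.max_distance - 1, 50)
            vals = [cfg.decay_value(d) for d in ds]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_unknown_decay_rejected(self):
        with pytest.raises(ValueError):
            ScoringConfig(decay="step")
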