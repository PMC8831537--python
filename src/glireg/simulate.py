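"""Synthetic limb-bud regulatory genomics data with planted truth.

Generates every input the analysis stages consume — gene models and TADs,
GLI binding regions (GBRs) with chromatin-mark peak sets, an H3K27ac
region x sample count matrix contrasting an HH-active and a constitutively
repressed genotype, a downregulated-gene expression table, per-sample
read placements for intron-retention analysis, and per-condition ATAC
footprints with motif hits — together with a :class:`SyntheticTruth`
record of everything planted, so recovery can be measured without any
external download.

Counts follow a negative binomial with variance ``mu * (1 + dispersion)``
(constant overdispersion relative to Poisson) and per-sample library-size
multipliers drawn log-uniformly from [0.5x, 2x], so the normalisation
stage is genuinely exercised.  Chromatin marks co-occur with GBRs
conditionally on a latent region class (poised / naive / repressed),
giving the classification stages non-trivial structure.  All randomness
flows from ``SimConfig.seed`` through per-stage child generators; no
global state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffenrich import CountMatrix
from .intervals import GeneModel, GenomicInterval, PeakSet, TADSet, assign_tad

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_assay_data",
    "generate_expression",
    "generate_retention_reads",
    "generate_footprints",
]

# child-generator stream ids, one per generation stage
_STREAM_GENOME = 1
_STREAM_ASSAY = 2
_STREAM_EXPRESSION = 3
_STREAM_RETENTION = 4
_STREAM_FOOTPRINT = 5

MARKS = ("atac", "k4me1", "k4me2", "k27me3", "k27ac_pre", "gli3_post")


def _default_cooccurrence() -> dict:
    # P(mark peak at region | latent class); GBRs sit mostly at poised,
    # accessible enhancers with low pre-HH H3K27ac
    return {
        "poised": {
            "atac": 0.95, "k4me1": 0.80, "k4me2": 0.80,
            "k27me3": 0.05, "k27ac_pre": 0.30, "gli3_post": 0.70,
        },
        "naive": {
            "atac": 0.30, "k4me1": 0.20, "k4me2": 0.20,
            "k27me3": 0.05, "k27ac_pre": 0.15, "gli3_post": 0.30,
        },
        "repressed": {
            "atac": 0.15, "k4me1": 0.10, "k4me2": 0.10,
            "k27me3": 0.80, "k27ac_pre": 0.02, "gli3_post": 0.15,
        },
    }


class ConfigurationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults are the study conditions used throughout the test suite:
    3,000 GBRs of which 10% are HH-responsive with a planted log2
    fold-change of −1 in the repressed genotype, 3 replicates per group,
    50 planted target genes among 550, footprint motif-containment
    frequencies 0.2 (pre-HH) vs 0.1 (post-HH repressed).
    """

    seed: int = 0
    # genome geometry
    n_chroms: int = 2
    chrom_length: int = 50_000_000
    n_genes: int = 550
    n_tads: int = 250
    # GBRs and counts
    n_gbrs: int = 3000
    gbr_width: int = 300
    frac_responsive: float = 0.10
    stray_responsive_frac: float = 0.10
    effect_log2fc: float = -1.0
    base_mean: float = 100.0
    nb_dispersion: float = 0.1
    n_reps_per_group: int = 3
    mark_cooccurrence: dict = field(default_factory=_default_cooccurrence)
    # target planting
    n_true_targets: int = 50
    target_max_distance: int = 100_000
    frac_decoy_down: float = 0.25
    promoter_mark_prob_target: float = 0.9
    promoter_mark_prob_other: float = 0.3
    # intron retention
    n_retention_genes: int = 100
    reads_per_gene: int = 1000
    read_length: int = 100
    retention_rate_range: tuple = (0.05, 0.6)
    retention_shift: float = 0.3
    frac_retention_shifted: float = 0.2
    # footprints
    n_footprints: int = 2000
    footprint_width: int = 20
    motif_width: int = 8
    motif_freq_by_condition: dict = field(
        default_factory=lambda: {"pre_hh": 0.2, "post_hh": 0.1}
    )

    def __post_init__(self) -> None:
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_tads", "n_gbrs",
            "gbr_width", "n_reps_per_group", "n_footprints",
            "footprint_width", "motif_width", "reads_per_gene", "read_length",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "frac_responsive", "stray_responsive_frac", "frac_decoy_down",
            "promoter_mark_prob_target", "promoter_mark_prob_other",
            "frac_retention_shifted",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        for cond, f in self.motif_freq_by_condition.items():
            if not 0 <= f <= 1:
                raise ConfigurationError(f"motif frequency for {cond} not in [0,1]")
        lo, hi = self.retention_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("retention_rate_range must be within [0, 1]")
        for cls, probs in self.mark_cooccurrence.items():
            for mark, p in probs.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(
                        f"mark_cooccurrence[{cls}][{mark}] not in [0, 1]"
                    )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SyntheticTruth:
    """Everything planted by the generators, for recovery scoring.

    Emitted alongside the data and never read by the analysis stages.
    """

    responsive_region_ids: list = field(default_factory=list)
    true_target_gene_ids: list = field(default_factory=list)
    region_latent_class: dict = field(default_factory=dict)
    region_group_means: dict = field(default_factory=dict)
    retention_rate_by_gene: dict = field(default_factory=dict)
    motif_freq_by_condition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------- genome


def generate_genome(cfg: SimConfig) -> tuple[list[GeneModel], TADSet]:
    """Non-overlapping gene models (2–10 exons each) and tiling TADs.

    Each chromosome is divided into per-gene slots; a gene occupies a
    random sub-interval of its slot, with an alternating exon/intron
    partition whose first and last segments are exons.  TADs tile each
    chromosome exactly, so every midpoint is assignable.
    """
    rng = cfg.rng(_STREAM_GENOME)
    genes_per_chrom = [
        cfg.n_genes // cfg.n_chroms + (1 if c < cfg.n_genes % cfg.n_chroms else 0)
        for c in range(cfg.n_chroms)
    ]
    genes: list[GeneModel] = []
    min_intron = cfg.read_length + 100
    for c, n_c in enumerate(genes_per_chrom):
        chrom = f"chr{c + 1}"
        if n_c == 0:
            continue
        slot = cfg.chrom_length // n_c
        if slot < 120 * min_intron:
            raise ConfigurationError(
                f"chromosome {chrom} too short for {n_c} genes"
            )
        for i in range(n_c):
            slot_start = i * slot
            gene_len = int(rng.integers(slot // 6, slot // 2))
            start = int(rng.integers(slot_start, slot_start + slot - gene_len))
            n_exons = int(rng.integers(2, 11))
            n_seg = 2 * n_exons - 1
            weights = rng.random(n_seg) + 0.2
            spare = gene_len - n_seg * min_intron
            lengths = (min_intron + np.floor(weights / weights.sum() * spare)).astype(int)
            lengths[-1] = gene_len - int(lengths[:-1].sum())
            pos = start
            exons = []
            for j, seg in enumerate(lengths):
                if j % 2 == 0:
                    exons.append(GenomicInterval(chrom, pos, pos + int(seg)))
                pos += int(seg)
            body = GenomicInterval(chrom, start, start + gene_len)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel("", body, strand, exons))
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    for i, g in enumerate(genes):
        gid = f"gene_{i + 1:04d}"
        g.gene_id = gid
        g.body = GenomicInterval(g.body.chrom, g.body.start, g.body.end, gid)

    tads_per_chrom = [
        cfg.n_tads // cfg.n_chroms + (1 if c < cfg.n_tads % cfg.n_chroms else 0)
        for c in range(cfg.n_chroms)
    ]
    tads = []
    k = 0
    for c, n_t in enumerate(tads_per_chrom):
        chrom = f"chr{c + 1}"
        bounds = np.linspace(0, cfg.chrom_length, n_t + 1).astype(int)
        for a, b in zip(bounds[:-1], bounds[1:]):
            k += 1
            tads.append(GenomicInterval(chrom, int(a), int(b), f"tad_{k:04d}"))
    return genes, TADSet(tads)


# ----------------------------------------------------------------- assays


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean * (1 + dispersion)."""
    r = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    return rng.negative_binomial(np.maximum(r, 1e-9), p)


def generate_assay_data(
    cfg: SimConfig, genes: list[GeneModel], tads: TADSet
) -> tuple[dict[str, PeakSet], CountMatrix, SyntheticTruth]:
    """GBRs, chromatin-mark peak sets, the H3K27ac count matrix and truth.

    Planted target genes each receive a cluster of HH-responsive GBRs
    within ``target_max_distance`` of the TSS inside the same TAD, forced
    accessible and H3K4me1-marked (guaranteed poised); a configurable
    fraction of responsive GBRs is scattered elsewhere.  Responsive
    regions carry ``effect_log2fc`` between the two genotypes in the
    count matrix; all other regions share group means.
    """
    rng = cfg.rng(_STREAM_ASSAY)
    n_resp = int(round(cfg.frac_responsive * cfg.n_gbrs))
    if cfg.n_true_targets > len(genes):
        raise ConfigurationError("more planted targets than genes")
    if cfg.n_true_targets > 0 and n_resp < cfg.n_true_targets:
        raise ConfigurationError("fewer responsive GBRs than planted targets")

    # planted targets, preferring distinct TADs
    gene_order = list(rng.permutation(len(genes)))
    targets: list[GeneModel] = []
    used_tads: set[str] = set()
    for idx in gene_order:
        if len(targets) == cfg.n_true_targets:
            break
        g = genes[idx]
        t = assign_tad(g.body, tads)
        if t is None or t in used_tads:
            continue
        targets.append(g)
        used_tads.add(t)
    for idx in gene_order:  # fall back when distinct TADs run out
        if len(targets) == cfg.n_true_targets:
            break
        g = genes[idx]
        if g not in targets and assign_tad(g.body, tads) is not None:
            targets.append(g)
    target_ids = sorted(g.gene_id for g in targets)

    n_stray = int(round(cfg.stray_responsive_frac * n_resp))
    n_planted = n_resp - n_stray if targets else 0
    if targets and n_planted < len(targets):
        n_planted = len(targets)
    n_stray = n_resp - n_planted

    tad_of_gene = {g.gene_id: next(t for t in tads if t.name == assign_tad(g.body, tads)) for g in targets}

    half = cfg.gbr_width // 2
    records = []  # (interval, responsive, latent_class, forced_poised)
    if targets:
        quota = [n_planted // len(targets)] * len(targets)
        for j in range(n_planted % len(targets)):
            quota[j] += 1
        for g, q in zip(targets, quota):
            tad = tad_of_gene[g.gene_id]
            lo = max(tad.start + half, g.tss - cfg.target_max_distance)
            hi = min(tad.end - half, g.tss + cfg.target_max_distance)
            if hi <= lo:
                raise ConfigurationError(
                    f"no room to plant GBRs near {g.gene_id}"
                )
            for _ in range(max(q, 1)):
                mid = int(rng.integers(lo, hi))
                iv = GenomicInterval(tad.chrom, mid - half, mid + half)
                records.append([iv, True, "poised", True])

    n_background = cfg.n_gbrs - len(records)
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chroms)]
    bg_chroms = rng.integers(0, cfg.n_chroms, n_background)
    bg_mids = rng.integers(half, cfg.chrom_length - half, n_background)
    stray_idx = set(rng.choice(n_background, size=min(n_stray, n_background), replace=False).tolist())
    for i in range(n_background):
        iv = GenomicInterval(chrom_names[bg_chroms[i]], int(bg_mids[i]) - half, int(bg_mids[i]) + half)
        responsive = i in stray_idx
        if responsive:
            cls = "poised" if rng.random() < 0.9 else "naive"
        else:
            cls = ["poised", "naive", "repressed"][
                int(rng.choice(3, p=[0.3, 0.5, 0.2]))
            ]
        records.append([iv, responsive, cls, False])

    records.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    region_ids = [f"gbr_{i + 1:05d}" for i in range(len(records))]
    gbr_intervals = [
        GenomicInterval(r[0].chrom, r[0].start, r[0].end, rid)
        for r, rid in zip(records, region_ids)
    ]

    truth = SyntheticTruth(
        responsive_region_ids=[rid for rid, r in zip(region_ids, records) if r[1]],
        true_target_gene_ids=target_ids,
        region_latent_class={rid: r[2] for rid, r in zip(region_ids, records)},
        motif_freq_by_condition=dict(cfg.motif_freq_by_condition),
    )

    # chromatin-mark peaks co-occurring with GBRs by latent class
    peak_sets: dict[str, PeakSet] = {"gli3_pre": PeakSet("gli3_pre", gbr_intervals, "simulated")}
    for mark in MARKS:
        ivs = []
        for rid, r in zip(region_ids, records):
            iv, _resp, cls, forced = r
            p = cfg.mark_cooccurrence[cls][mark]
            hit = rng.random() < p
            if forced and mark in ("atac", "k4me1"):
                hit = True
            if hit:
                w = int(rng.integers(150, 400))
                mid = iv.midpoint + int(rng.integers(-half // 2, half // 2 + 1))
                ivs.append(GenomicInterval(iv.chrom, max(0, mid - w), mid + w))
        if mark != "gli3_post":
            # background peaks away from GBRs
            n_bg = cfg.n_gbrs // 4
            for c, mid in zip(
                rng.integers(0, cfg.n_chroms, n_bg),
                rng.integers(400, cfg.chrom_length - 400, n_bg),
            ):
                w = int(rng.integers(150, 400))
                ivs.append(GenomicInterval(chrom_names[c], int(mid) - w, int(mid) + w))
        ivs.sort(key=lambda v: (v.chrom, v.start, v.end))
        peak_sets[mark] = PeakSet(mark, ivs, "simulated")

    # H3K4me3 promoter peaks (gene weighting input)
    k4me3 = []
    target_set = set(target_ids)
    for g in genes:
        p = (
            cfg.promoter_mark_prob_target
            if g.gene_id in target_set
            else cfg.promoter_mark_prob_other
        )
        if rng.random() < p:
            w = int(rng.integers(300, 800))
            k4me3.append(
                GenomicInterval(g.body.chrom, max(0, g.tss - w), g.tss + w)
            )
    peak_sets["k4me3"] = PeakSet("k4me3", k4me3, "simulated")

    # H3K27ac count matrix: active vs repressed genotype
    n = cfg.n_reps_per_group
    samples = [f"active_{i + 1}" for i in range(n)] + [
        f"repressed_{i + 1}" for i in range(n)
    ]
    group_of = {s: ("g1_active" if s.startswith("active") else "g2_repressed") for s in samples}
    lib_mult = 2.0 ** rng.uniform(-1.0, 1.0, size=2 * n)
    base = cfg.base_mean * 2.0 ** rng.normal(0.0, 0.5, size=len(records))
    resp_mask = np.array([r[1] for r in records])
    mean_active = base
    mean_repressed = np.where(resp_mask, base * 2.0 ** cfg.effect_log2fc, base)
    counts = np.empty((len(records), 2 * n), dtype=int)
    for j, s in enumerate(samples):
        mu = (mean_active if group_of[s] == "g1_active" else mean_repressed) * lib_mult[j]
        counts[:, j] = _nb_counts(rng, mu, cfg.nb_dispersion)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(region_ids, name="region_id"), columns=samples),
        library_sizes=pd.Series(lib_mult * 1e6, index=samples),
        group_of=group_of,
    )
    truth.region_group_means = {
        rid: [float(a), float(b)]
        for rid, a, b in zip(region_ids, mean_active, mean_repressed)
    }
    return peak_sets, cm, truth


# ------------------------------------------------------------- expression


def generate_expression(
    cfg: SimConfig, genes: list[GeneModel], truth: SyntheticTruth
) -> pd.DataFrame:
    """Differential-expression table (gene_id, log2fc, fdr).

    Planted targets are strongly downregulated in the repressed genotype;
    a ``frac_decoy_down`` share of the remaining genes is downregulated
    too (indirect effects); all other genes are clearly non-significant.
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    target_set = set(truth.true_target_gene_ids)
    rows = []
    for g in genes:
        if g.gene_id in target_set:
            lfc = -abs(rng.normal(1.5, 0.3))
            fdr = float(rng.uniform(1e-4, 0.01))
        elif rng.random() < cfg.frac_decoy_down:
            lfc = -abs(rng.normal(1.0, 0.5))
            fdr = float(rng.uniform(1e-4, 0.04))
        else:
            lfc = float(rng.normal(0.0, 0.5))
            fdr = float(rng.uniform(0.1, 1.0))
        rows.append({"gene_id": g.gene_id, "log2fc": round(float(lfc), 4), "fdr": round(fdr, 6)})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- retention


def generate_retention_reads(
    cfg: SimConfig, genes: list[GeneModel], truth: SyntheticTruth | None = None
) -> tuple[dict[str, PeakSet], dict[str, dict[str, float]]]:
    """Per-sample read intervals with planted intron-retention rates.

    The first ``n_retention_genes`` genes with a usable intron are
    simulated.  Each sample gets ``reads_per_gene`` gene-body reads per
    gene; a Binomial(M, r) share is placed wholly inside introns, the
    rest overlap an exon.  Group 2 ("late") rates are shifted by
    ``retention_shift`` for a planted gene subset.  Returns
    (reads by sample, truth rates {gene: {group: rate}}); the rates are
    also recorded on ``truth`` when given.
    """
    rng = cfg.rng(_STREAM_RETENTION)
    usable = [
        g
        for g in genes
        if any(i.length >= cfg.read_length + 2 for i in g.introns())
    ]
    if len(usable) < cfg.n_retention_genes:
        raise ConfigurationError(
            f"only {len(usable)} genes have introns long enough for reads"
        )
    chosen = usable[: cfg.n_retention_genes]
    n_shift = int(round(cfg.frac_retention_shifted * len(chosen)))
    shifted = set(
        rng.choice(len(chosen), size=n_shift, replace=False).tolist()
    )
    lo, hi = cfg.retention_rate_range
    base_rates = rng.uniform(lo, hi, size=len(chosen))

    n = cfg.n_reps_per_group
    samples = [f"early_{i + 1}" for i in range(n)] + [f"late_{i + 1}" for i in range(n)]
    rates_truth: dict[str, dict[str, float]] = {}
    reads_by_sample: dict[str, list[GenomicInterval]] = {s: [] for s in samples}
    rl = cfg.read_length
    for gi, g in enumerate(chosen):
        r_early = float(base_rates[gi])
        r_late = min(0.95, r_early + cfg.retention_shift) if gi in shifted else r_early
        rates_truth[g.gene_id] = {"early": round(r_early, 6), "late": round(r_late, 6)}
        introns = [i for i in g.introns() if i.length >= rl + 2]
        if not introns and (r_early > 0 or r_late > 0):
            raise ConfigurationError(f"gene {g.gene_id} has no usable intron")
        intron_w = np.array([i.length for i in introns], dtype=float)
        intron_w /= intron_w.sum()
        exon_w = np.array([e.length for e in g.exons], dtype=float)
        exon_w /= exon_w.sum()
        for s in samples:
            r = r_early if s.startswith("early") else r_late
            m = cfg.reads_per_gene
            n_intronic = int(rng.binomial(m, r))
            which_introns = rng.choice(len(introns), size=n_intronic, p=intron_w)
            which_exons = rng.choice(len(g.exons), size=m - n_intronic, p=exon_w)
            out = reads_by_sample[s]
            for k in which_introns:
                intron = introns[k]
                start = int(rng.integers(intron.start, intron.end - rl + 1))
                out.append(GenomicInterval(g.body.chrom, start, start + rl))
            for k in which_exons:
                exon = g.exons[k]
                start = int(
                    rng.integers(max(0, exon.start - rl + 1), exon.end)
                )
                out.append(GenomicInterval(g.body.chrom, start, start + rl))
    peaksets = {
        s: PeakSet(s, sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)), "simulated reads")
        for s, ivs in reads_by_sample.items()
    }
    if truth is not None:
        truth.retention_rate_by_gene = rates_truth
    return peaksets, rates_truth


# -------------------------------------------------------------- footprints


def generate_footprints(
    cfg: SimConfig,
) -> tuple[dict[str, PeakSet], PeakSet, dict[str, float]]:
    """Per-condition footprint sets and a shared motif-hit set.

    Footprints are placed on non-overlapping slots (disjoint across
    conditions) so a hit planted in one footprint can never fall inside
    another; each footprint contains a motif hit with its condition's
    configured probability.
    """
    rng = cfg.rng(_STREAM_FOOTPRINT)
    conds = sorted(cfg.motif_freq_by_condition)
    total = cfg.n_footprints * len(conds)
    stride = cfg.footprint_width * 5
    n_slots = cfg.chrom_length // stride
    if n_slots < total:
        raise ConfigurationError("chromosome too short for requested footprints")
    slots = rng.choice(n_slots, size=total, replace=False)
    footprints: dict[str, PeakSet] = {}
    hits: list[GenomicInterval] = []
    for ci, cond in enumerate(conds):
        freq = cfg.motif_freq_by_condition[cond]
        ivs = []
        for slot in slots[ci * cfg.n_footprints : (ci + 1) * cfg.n_footprints]:
            start = int(slot) * stride
            fp = GenomicInterval("chr1", start, start + cfg.footprint_width)
            ivs.append(fp)
            if rng.random() < freq:
                hs = int(rng.integers(fp.start, fp.end - cfg.motif_width + 1))
                hits.append(GenomicInterval("chr1", hs, hs + cfg.motif_width))
        ivs.sort(key=lambda v: (v.chrom, v.start))
        footprints[cond] = PeakSet(f"footprints_{cond}", ivs, "simulated")
    hits.sort(key=lambda v: (v.chrom, v.start))
    return footprints, PeakSet("motif_hits", hits, "simulated"), dict(cfg.motif_freq_by_condition)
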