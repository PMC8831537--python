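# Methods

`glireg` models a developmental gene-regulation setting: a transcriptional
repressor (a GLI-family factor in its repressor form) binds thousands of
genomic regions, and upon a signalling switch (Hedgehog activation) a subset
of those regions loses an active histone mark (H3K27ac) while nearby target
genes are transcriptionally repressed. The package provides (i) a synthetic
genome and assay generator with fully recorded ground truth and (ii) the
analysis pipeline that recovers that truth: differential enrichment, enhancer
state classification, weighted target ranking, intron-retention metrics, and
footprint motif enrichment. This document records the statistical model, the
default parameters, and the deliberate design decisions behind both halves.

## Genome model

All intervals are 0-based, half-open `[start, end)` (BED convention). An
overlap means at least 1 bp shared (`min_bp=1` by default). A gene model is a
body interval plus an alternating exon/intron partition whose first and last
segments are exons; the TSS is `body.start` on the + strand and `body.end - 1`
on the − strand. Region–gene distance is measured from the region midpoint
(`(start + end) // 2`) to the TSS. TADs tile each chromosome without gaps;
a region belongs to the TAD containing its midpoint, with half-open
assignment so a midpoint exactly at a TAD boundary belongs to the next TAD.

## Synthetic data

Every generator draws from `numpy.random.default_rng([seed, stream_id])` with
a distinct stream id per stage (genome = 1, assays = 2, expression = 3,
retention = 4, footprints = 5), so stages are independently reproducible and
adding a stage never perturbs another stage's draws.

**Genome** (`generate_genome`). Each chromosome is split into per-gene slots;
a gene occupies a random sub-interval of its slot with 2–10 exons. Defaults:
2 chromosomes × 50 Mb, 550 genes, 250 TADs.

**Regions and marks** (`generate_assay_data`). 3,000 bound regions (width
300 bp) carry a latent class (`poised`, `naive`, `repressed`) that drives
mark co-occurrence (ATAC, H3K4me1/2, H3K27me3, H3K27ac, post-switch
binding). 10% of regions are "responsive": their H3K27ac count mean is
multiplied by `2^effect_log2fc` (default −1) in the repressed condition.
Responsive regions are not scattered uniformly: ~90% are planted within
100 kb of the 50 designated target genes (in the same TAD), mirroring the
empirical clustering of signal-responsive enhancers around their targets; the
remaining ~10% are stray. Planted regions are forced accessible and
H3K4me1-marked (poised).

**Count noise.** H3K27ac counts are negative binomial in the NB1
parameterization, `var = mu * (1 + dispersion)` with `dispersion = 0.1`,
sampled as `rng.negative_binomial(n = mu/phi, p = 1/(1+phi))`. This is a
deliberate choice over the NB2 convention (`var = mu + alpha * mu^2`): at
`alpha = 0.1` and `mu ≈ 100`, NB2 implies a per-replicate log2-scale SD of
roughly 0.48, for which a 3-vs-3 comparison of a 1-log2FC effect has power of
only ~15% after FDR control — no method could recover most planted effects.
NB1 at `phi = 0.1` is mild over-Poisson noise under which the planted effect
is recoverable (measured recall ≈ 0.97 at defaults), which matches the
intended role of the simulation: validating the analysis code, not stress
testing it. Per-region baselines are `base_mean * 2^N(0, 0.5)` and per-sample
library sizes vary by `2^U(-1, 1)`.

**Expression, retention reads, footprints.** Target genes enter the
differential-expression table as significantly down-regulated
(`log2fc = -|N(1.5, 0.3)|`, FDR `U(1e-4, 0.01)`); 25% of non-targets are
down-regulated decoys. Retention reads are placed per gene with a planted
intronic share (the retention rate), shifted by +0.3 in the late condition
for 20% of genes. Footprints (2,000 per condition, width 20) are spatially
disjoint across conditions; a motif hit is placed fully inside a footprint
with a per-condition frequency (defaults 0.2 pre-switch, 0.1 post-switch).

The generators emulate interval geometry, count noise, and planted effect
structure. They do not emulate read-level sequence content, mappability,
fragment-length distributions, peak-calling uncertainty, or correlated
replicate structure.

## Differential enrichment

Counts are normalized as `log2(count * (mean_lib / lib_s) + 1)` (pseudo-count
1; a zero count maps to exactly 0 regardless of library size). Group
comparison uses a moderated two-group t-test: per-region pooled variance
`s^2`, a prior variance `s0^2` equal to the mean of the per-region pooled
variances, prior degrees of freedom `d0 = 4`, posterior variance
`(d0*s0^2 + df*s^2) / (d0 + df)`, and a t reference with `d0 + df` degrees of
freedom. Setting `prior_df = 0` recovers the ordinary pooled t-test exactly
(verified against `scipy.stats.ttest_ind` to 1e-10 in tests). The log2 fold
change is group2 − group1 with groups ordered lexicographically. P-values are
adjusted by Benjamini–Hochberg step-up; regions with FDR < alpha (default
0.05) are called differential, signed `up`/`down`.

## Enhancer states and responsiveness

A region is **poised** iff it is accessible (ATAC) and carries H3K4me1 or
H3K4me2. A bound region is **Hh-responsive** iff its H3K27ac is
significantly reduced (FDR < alpha, direction `down`). Gene competence is
classified from promoter (TSS ± 2 kb) marks with precedence: **competent**
(repressor-bound promoter without H3K27me3) over **bivalent** (H3K27me3 with
H3K27ac) over **prc2_repressed** (H3K27me3 without H3K27ac) over
unclassified.

## Target ranking

Each down-regulated significant gene g gets
`score(g) = sum over linked regions r of w_gbr(r) * w_gene(g) * decay(d(r, g))`,
where a region links to a gene iff the midpoint–TSS distance is at most
500 kb and both lie in the same TAD. Region weights: poised responsive = 2,
other responsive = 1 (non-responsive regions are excluded). Gene weights:
promoter-marked (H3K4me3) = 2, otherwise 1. The weight orderings
(poised > base, marked > base) are enforced by the configuration class.
Decay families — linear, quadratic, exponential (scale 100 kb) — all satisfy
`decay(0) = 1`, strictly decreasing, and 0 at or beyond the maximum distance.
Ties are broken lexicographically by gene id, making the ranking a
deterministic function of the input sets, invariant to input row order.

## Intron retention

For a gene, `N` = reads overlapping at least one exon by ≥ 1 bp, `M` = reads
overlapping the gene body. The retention rate is `1 − N/M`, computed exactly
as a `Fraction` before conversion to float; `M = 0` means the gene is not
assessable (an error at the statistic level, `NaN` in tables). Differential
retention between conditions reuses the moderated t machinery on per-sample
rates. The per-read classification (`count_reads`) is the definition of
record; a vectorized `searchsorted`-based path (`_counts_for_sample`) is used
at scale and is tested to agree read-for-read with it.

## Footprint enrichment

For each condition, the motif fraction is the share of footprints containing
at least one motif hit *strictly within* the footprint (containment, not mere
overlap). The enrichment ratio is `fraction_a / fraction_b`; significance
comes from a two-sided Fisher exact test on the 2×2 contingency table
(with/without hit × condition), computed by the probability-mass method in
exact integer arithmetic: numerators `C(r1, a) * C(r2, c1−a)` are summed as
Python ints over all tables whose numerator does not exceed the observed one,
then divided once by `C(n, c1)`. Degenerate margins give p = 1. Exact
integer comparison avoids float ties near equal-probability tables;
`scipy.stats.fisher_exact` is used in tests as an independent cross-check
only.

## Determinism and numerics

Pipeline outputs are written with sorted JSON keys, fixed float formatting
(`%.6g` in JSON reports, 6-decimal rounding in score tables), and
lexicographically sorted rows; `report.json` records a SHA-256 digest of
every emitted file. Two runs with the same configuration and seed are
byte-identical. P-values are clipped to `[tiny, 1]`; infinite t statistics
(zero pooled variance with a nonzero difference) are handled explicitly.

## Open decisions and limitations

- The retention statistic is read as `1 − (N/M)`; under the alternative
  reading `(1 − N)/M` the quantity would not be a rate (it can be negative
  and is not bounded by 1), so the rate reading is used throughout.
- The moderated test uses a fixed prior (`d0 = 4`, `s0^2` = mean pooled
  variance) rather than an empirical-Bayes fit of the prior; with three
  replicates per group this is a pragmatic stabilizer, not an estimate.
- The ranking score is a heuristic prioritization, not a calibrated
  probability; its guarantees are ordinal (the ordering properties in the
  test suite), not metric.
- Recovery figures quoted above (recall ≈ 0.97, precision@50 ≈ 0.93) are
  measured on the default configuration via `scripts/acceptance.py` and will
  vary with seed and configuration.
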