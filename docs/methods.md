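# Methods

This note documents the statistical models, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Differential testing engine

Both the loop and the expression analyses share one engine
(`chromalink.stats`).

**Library normalization.** Between-sample scaling uses the trimmed mean
of M-values (TMM). For sample *j* against a reference sample *r*
(chosen as the sample whose 75th-percentile/library-size ratio is
closest to the mean of those ratios), M-values
M = log₂((y_j/N_j)/(y_r/N_r)) and average intensities
A = ½·log₂((y_j/N_j)(y_r/N_r)) are computed over features nonzero in
both samples. After discarding the outer 30% of M-ranks and 5% of
A-ranks (two-sided), the scaling factor is 2^f with f the mean of the
retained M-values weighted by the inverse of the approximate binomial
variance (1/y − 1/N summed over the two samples); factors are rescaled
to geometric mean 1. The implementation reproduces edgeR's
`calcNormFactors(method="TMM")` to ≈1e-10 (checked by an Rscript
cross-test). Loop strengths are continuous, not integer; they enter the
same formulas with library size defined as the column sum. A note on an
idealized invariance: rescaling a single sample's column cancels
exactly in the M-values but not in the precision weights, so TMM
factors are only approximately invariant to pure depth changes (the
test asserts 10% stability; the exact-zero case of identical columns
yields factors of exactly 1).

**Log transform.** log₂((count + 0.5) / (N_j · TMM_j) × 10⁶) — the
conventional counts-per-million bridge between count normalization and
linear modeling; the 0.5 prior keeps zeros finite.

**Variable-feature selection (loops only).** The n_top = 100,000 rows
with the largest sample SD (ddof = 1) of the log matrix; ties keep input
order. Desk-scale datasets have fewer loops, in which case selection is
a no-op. Multiple testing is corrected within the tested subset only.

**Two-group fit.** logFC = mean(relapse) − mean(diagnosis) with pooled
residual variance on n − 2 df. This equals OLS on the two-column design
matrix (tested against `numpy.linalg.lstsq`).

**Empirical-Bayes moderation.** The marginal distribution of residual
variances is matched to s₀²·F(d, d₀) by moments of log s²:
with e = log s² − ψ(d/2) + log(d/2), the prior df solve
ψ′(d₀/2) = var(e) − ψ′(d/2) via a monotone Newton inversion of the
trigamma function, and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When
the observed spread of log s² does not exceed the sampling floor, d₀ is
+∞ and every variance shrinks fully to s₀². The degenerate input of
exactly equal variances is special-cased to s₀² = that common value
(the bias-correction term assumes sampling spread that such input does
not have). Posterior variances are the convex combination
(d₀s₀² + d·s²)/(d₀ + d); the moderated t uses d₀ + d df (normal when
infinite). Forcing d₀ = 0 recovers the ordinary t-statistic (tested
against `scipy.stats.ttest_ind`). The whole path reproduces limma's
`eBayes(lmFit(...))` to ≈1e-8 on a shared fixture.

**Precision weighting for counts (expression only).** Log-CPM variances
depend on expression level. Before moderation, the quarter-power of
each gene's residual variance is smoothed by a centered running median
(window ≈ 10% of genes) along average log-expression, and variances are
rescaled by trend⁻⁴ — i.e. pooled as ratios to the trend, then mapped
back. This per-gene analog of precision weighting (closer to
limma-trend than to observation-level voom weights) stabilizes the
prior fit; it is the default for expression and off for loops, whose
log-normal strengths are close to homoscedastic already. A variance
floor of 1e-8 precedes moderation so duplicate-free synthetic data
cannot produce log(0).

**FDR.** Step-up Benjamini–Hochberg with monotonicity enforcement and a
final clamp to p_adj ≥ p guarding against 1-ulp float loss. Verified
against the textbook definition (min over j ≥ i of m·p(j)/j) and
against `statsmodels.multipletests`.

**Thresholds.** Loops: adjusted p < 0.1, partitioned by sign of logFC;
no fold-change cutoff is applied (none is part of the loop-selection
convention adopted here). Expression: adjusted p < 0.1 **and**
|log₂FC| > 1, strict inequalities. The DE universe — also the pool for
random gene sets — is genes with CPM > 1 in ≥ 2 samples; an expression
filter prevents degenerate fold changes among never-expressed genes and
is configurable.

## Open-chromatin states

Reproducibility is replicate-anchored: the reference (first-listed)
replicate's peaks that overlap the second replicate at ≥ 1 bp are the
state's "common" peaks, keeping called peak boundaries intact rather
than intersecting or merging them. State-specific peaks remove, as
whole peaks, any common peak overlapping the other state's common set;
"shared" regions are common-diagnosis peaks overlapping common-relapse,
reported with diagnosis-side coordinates (recorded in the summary
metadata, since a side must be chosen). Consequences tested as
invariants: the two specific sets can never overlap, the derivation is
idempotent, and |common| = |specific| + |shared| on the diagnosis side.

## Integration and the permutation null

Anchors of one state's significant loops (deduplicated by exact
coordinates — overlapping but unequal anchors stay distinct) are kept
if ≥ 1 state-specific peak overlaps them. Genes are linked to an
accessible anchor when the anchor extended by 20 kb on both sides
overlaps the gene body by ≥ 1 bp. The loop's other end is the gene's
distal anchor; if both ends of a loop link the same gene, the farther
end is distal. One record per (gene, loop), carrying the gene's logFC
and whether the distal anchor overlaps a repressive-mark interval.

**Enrichment vs random gene sets.** The observed statistic is the
median logFC of the linked upregulated genes (median rather than mean
for robustness at the small set sizes involved; mean available via an
argument). Null sets are 10 simple random samples without replacement,
size-matched, drawn from the filtered gene universe excluding the
observed set (excluding avoids self-inflation). Ties count as
exceedances; p = (#null ≥ observed + 1)/11. The universe can instead be
restricted to upregulated genes via the `universe` argument.

**Silencer-loss permutation test.** Candidates are
diagnosis-state records whose gene is significantly upregulated. The
statistic is the fraction of candidate genes with ≥ 1 repressive-marked
distal anchor. The null preserves interval width and chromosome
composition: each distal anchor is replaced by an equal-width interval
uniform on its chromosome (chromosome lengths are an explicit input),
and the fraction is recomputed; p = (k + 1)/(n_perm + 1) with ties as
exceedances, n_perm = 10,000 by default. The add-one estimator at zero
exceedances, truncated to three significant figures, prints as
9.99 × 10⁻⁵ — the convention the reported p-values follow. Calibration
is tested: when marks are themselves random, the p-values over 200
replicate datasets are not anti-conservative (one-sided KS at 1%).
Because several genes can share a distal anchor (dense gene
neighborhoods), null fractions move in correlated jumps; the test
handles this correctly since the permutation resamples anchors, not
genes.

**Report.** A versioned JSON (plus a flattened TSV) with per-state
anchor/peak/gene counts, enrichment and permutation results, and the
tri-omic gene list — genes significant in expression that are also
linked through a state-specific accessible anchor to a state-specific
loop. All lists are sorted and all seeds recorded, so identical
configs and seeds give byte-identical reports (timestamps are confined
to run.log).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes
for a 2-diagnosis/2-relapse design, at a size that runs end to end in
well under a minute on one CPU (defaults: 2 chromosomes × 10 Mb, 20,000
loops, 5% differential at 2 log₂ units, log₂-scale noise SD 0.3, 5,000
genes, 200 DE at |log₂FC| 2, NB dispersion 0.1, peak reproducibility
0.9, 10 silencer-loss genes, seed 1337).

* **Loops.** Anchor pairs 100 kb–2 Mb apart, 5 kb anchors. Strengths
  are log-normal: a per-loop baseline (log₂ mean 3.3, SD 1.0), i.i.d.
  log₂ noise (SD `loop_noise_sd`, interpreted on the log₂ scale — the
  scale of every downstream statistic), a per-sample depth factor
  (log₂ SD 0.25) that exercises TMM, and for planted loops a
  2^effect multiplier on the stronger group's samples.
* **Genes and counts.** Genes on a regular grid (bodies 1–3 kb),
  baseline means log-normal around 300 counts. Counts are
  negative-binomial with common dispersion (var = m + αm²); relapse
  means of planted DE genes are shifted by 2^±log₂FC. DE genes are
  drawn from genes with baseline mean ≥ 30, and the multi-omically
  wired subset from means ≥ 300, so planted fold changes are
  identifiable rather than buried in shot noise.
* **Wiring.** Silencer-loss genes (plus a few additional upregulated
  and downregulated genes) get a dedicated differential loop whose
  promoter anchor covers the TSS and whose distal anchor is ≥ 100 kb
  away, with state-specific peaks planted in both anchors; repressive
  marks cover the silencer genes' distal anchors exactly, on top of
  ~1% uniform background coverage (small but nonzero, so the
  permutation null is informative). Each planted peak appears in both
  of its state's replicates with probability `peak_reproducibility`,
  otherwise in one.
* **Geometry.** All planted peaks are placed mutually non-overlapping
  (rejection sampling; impossible geometry raises a "geometry
  overflow" error), so planted state labels are unambiguous under the
  whole-peak subtraction rule.

**What it does not emulate:** distance-decay of contact frequency,
peak-boundary jitter between replicates, mappability/blacklist
structure, realistic gene-density variation (genes sit ~4 kb apart at
desk scale, so a 20 kb window links several genes per anchor — a
deliberately adversarial density for the linkage logic), patient-level
pairing, and copy-number or translocation effects. Passing tests
therefore demonstrate correctness of the statistical machinery and the
integration chain under the assumed generative model, not performance
on real AML data.

**Truth tables and attainable recovery.** The truth lists planted
differential loops, state peaks (with their realized reproducibility),
DE genes, silencer-loss genes, and "tri-omic" genes — wired DE genes
whose promoter-anchor peak reproduced in both replicates. Recovery of a
silencer-loss gene requires its peak to reproduce (probability 0.9),
its loop to be called, and its gene to pass the DE thresholds; with
2v2 negative-binomial counts at dispersion 0.1 the realized fold change
of a planted |log₂FC| = 2 gene occasionally falls below the cutoff, so
end-to-end recovery is binomial around ~8–9 of 10 rather than
deterministic. The tests assert ≥ 8/10 at the default seed, that
recovery conditional on upstream calls is lossless (the integration
chain itself never drops a gene), and ≥ 60% unconditional tri-omic
recall.

## Numerical conventions and edge cases

* Coordinates are 0-based half-open everywhere; abutting intervals do
  not overlap; the overlap threshold is ≥ 1 bp (no reciprocal-fraction
  requirement). Chromosome names match exactly; a validation warning
  fires when two inputs share no chromosome name.
* Anchors are canonically ordered within a loop; loop ids are unique
  per file, synthesized from coordinates when absent.
* Loops observed in only one sample are retained with zeros elsewhere
  (no presence filter); the variance ranking naturally promotes them.
* Random substreams derive from the master seed via
  `numpy.random.SeedSequence(master, spawn_key=(k,))`, recorded in all
  outputs; every derived seed is < 2³¹.
* `fit_two_group` requires ≥ 2 samples per group; `squeeze_var`
  requires ≥ 10 positive variances (else full shrinkage to the mean)
  and refuses all-zero variances with a pointer to the variance floor.
* Sample SD uses ddof = 1 throughout.

## Known limitations

* Only two-group contrasts; no covariates, pairing, or weights beyond
  the per-gene trend.
* The permutation null for silencer loss (width- and
  chromosome-matched uniform placement) is one defensible
  exchangeability choice; alternatives (e.g. distance-matched or
  GC-matched placement) are not implemented.
* Peak-state derivation is presence/absence overlap, not count-based
  differential accessibility, and depends on the chosen reference
  replicate (configurable, first-listed by default).
* The stage-wise `integrate` command requires the per-state loop BEDPE
  files written by `diffloops`, since anchor BED files alone cannot
  reconstruct which anchors pair into loops.
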