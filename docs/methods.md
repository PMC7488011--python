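# Methods

## The resampling framework

All analyses share one primitive: each stratum (an exposure group,
optionally restricted to one fetal sex and one time point) is resampled
with replacement at exactly its own sample size, independently per
stratum, for B iterations. The statistic of interest is recomputed on
every resampled cohort and the analysis reports a property of the
resulting distribution — a proportion of significant iterations, a
median with percentile interval, or a count distribution. The premise
is the usual bootstrap one: the empirical distribution of the stratum
stands in for its population, so the spread of the recomputed statistic
estimates the stability of the original estimate. This replaces
multiple-testing correction in the stability analyses by design; no
FDR/Bonferroni step is applied anywhere.

RNG policy: a master seed spawns named child streams ("anova",
"ancova", "effect", "corr", "calibration", "simulate"); within a
stream, the draw for (stratum, iteration) is a pure function of
`(seed, stream, stratum, iteration)`. Adding analyses, reordering
evaluation, or chunking the vectorised code therefore never perturbs
existing results. One shared draw per (stratum, iteration) is reused
across all miRNAs; the marginal distribution of every per-miRNA
statistic is identical to looping per miRNA, and the vectorised
sums-of-squares path is what keeps B = 2000 × 150 miRNAs × 12 strata
interactive. The scalar functions plus per-miRNA stream names provide
a strict per-miRNA audit path.

## Statistics

* **ANOVA**: one-way fixed effects, p from F = (SSB/df_b)/(SSW/df_w).
  Iterations in which a resampled group has zero within-group variance
  count as non-significant (p = 1) rather than being redrawn, keeping
  the iteration count fixed at B.
* **ANCOVA**: extra-sum-of-squares F test of `value ~ GA + group`
  against `value ~ GA` (type-II style drop test). The covariate is the
  gestational age at the blood draw matching the analysed time point
  (GA_bd1 at T2, GA_bd2 at T3); a "both" option includes the two draws.
* **Stability classification**: a miRNA is sex-specific for a sex iff
  its sex-stratum proportion of significant iterations strictly exceeds
  both the aggregated proportion and 0.5. Both inequalities are strict;
  ties fail. A miRNA whose aggregated proportion already exceeds 0.5
  can still be classified if a stratum strictly improves on it (a
  `require_agg_below` switch restores the capped reading).
* **Hedges' g**: J·(x̄−ȳ)/s_p with J = 1 − 3/(4N−9), pooled-variance
  s_p. Computed on ΔCt, so positive g means higher ΔCt — *lower*
  abundance — in the first (exposed) group. Percentile CIs use linear
  interpolation between order statistics (numpy default). Bootstrap
  draws with zero pooled SD contribute g = 0.
* **Correlation network**: Pearson r with two-sided p from
  t = r·sqrt((n−2)/(1−r²)). Constant columns (possible under
  resampling duplicates) yield r = 0, p = 1 — non-significant — so
  counts always refer to the same fixed pair universe; |r| = 1 p-values
  clamp to the smallest positive float. The bootstrap count path uses
  the equivalent |r| > r_crit(α, n) threshold instead of materialising
  p matrices. The count-exceedance test is one-sided by construction:
  p = 1 − #{exposed counts strictly > reference mean}/B, ties count as
  not exceeding.
* **Partial correlation**: correlation of least-squares residuals after
  regressing each miRNA on [1, covariates].
* **Freeman–Halton Fisher exact**: two-sided p = sum of conditional
  (multivariate hypergeometric) probabilities of all margin-compatible
  tables with probability ≤ the observed one (relative tolerance 1e-7
  absorbs floating-point ties). Tables are enumerated by
  margin-constrained recursion over rows (the table is oriented so the
  shorter dimension indexes rows); `auto` mode switches to a seeded
  Monte Carlo (margin-fixed tables from `scipy.stats.random_table`,
  default 10⁶ draws, add-one p estimate with standard error) when the
  estimated enumeration exceeds 2·10⁵ states — in the bundled
  demographic tables this selects Monte Carlo for the 5×3
  socioeconomic and 4×3 smoking tables, exact traversal for the rest.
* **Kruskal–Wallis**: delegated to scipy (tie-corrected H, χ²_{k−1}
  p); all-identical data returns (0, 1).

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume,
with defaults fixed to the study conditions:

* **Layout**: 161 pregnancies over two time points with per-cell counts
  (T2: UE 17M/8F, HEua 7M/12F, HEa 11M/13F; T3: UE 22M/14F, HEua
  9M/14F, HEa 16M/18F).
* **Ct model**: Ct_ij = base_i + shift_j + slope_i·(GA_j − ḠA) +
  planted shifts + 1.5·u_ij, with base_i ~ U(22, 35) cycles, per-sample
  technical shift ~ N(0, 1) Ct (removed exactly by global-mean
  normalization), gestational ages from N(18.88, 4.93) and
  N(33.08, 2.42) weeks clipped to [10, 42], residual scale 1.5 Ct. The
  paper panel's Ct distribution is not published; base range and noise
  SD are package choices exposed in `SimConfig`.
* **Residual structure** u_ij (unit variance per column):
  - non-member columns load on a global latent factor with loading
    ±0.55 (random sign), giving pairwise correlations of ±0.30 —
    circulating panels are broadly cross-correlated even in unexposed
    pregnancies, and the unexposed groups' published significant-pair
    counts sit far above the α floor;
  - the 70 co-secretion member columns follow a one-factor model with
    stratum-dependent loading: 0.45 at baseline (the block exists in
    everyone), 0.92 in HEa-female cells at both time points, 0.86 in
    HEua-female at T2 only, 0.84 in HEa-male at T3 only, plus a ±0.35
    background loading. Half the members are annotated to chromosome X,
    the rest alternate over chromosomes 6 and 21. Loadings were
    calibrated once against the published per-cell significant-pair
    counts (sample statistics, not test outcomes) and then frozen; the
    achieved per-cell fractions are roughly 60–85% of the published
    ones with exposed/UE ratios of 1.6–3.6;
  - planted-effect columns carry no background loading, so a planted
    shift of s standardized units materialises as Hedges' g ≈ s.
* **Detection dropout**: per-miRNA non-detection probability 0.05 for
  75% of the 200-assay candidate panel and 0.60 for the rest, so the
  80% expression filter retains ≈ 150 assays. Ground-truth columns
  (planted effects, factor members) are generated fully detected: an
  imputed Ct = 45 is a > 10 SD outlier that would silently change the
  planted effect size. Undetected wells are emitted as
  missing-with-flag; the 45 substitution is preprocessing's job.

What the generator does **not** emulate: hemolysis and plate effects,
inter-run calibration, heavy-tailed or miRNA-specific Ct noise,
longitudinal within-subject correlation between T2 and T3 (subjects
are independent across time points), and the block structure of real
chromosomal miRNA clusters beyond the single planted factor. Passing
recovery tests therefore demonstrate that the *pipeline* recovers the
planted structure at the study's sample sizes under Gaussian
assumptions — not that real plasma data meet those assumptions.

## Numerical and design choices

* Expression filter: "detected in ≥ 80% of samples" is computed over
  all samples pooled by default (the collective reading); a per-group
  mode retains an assay only if every group clears the threshold.
  Exactly 80% is retained (boundary inclusive). Detection is an input
  flag, never a Ct cutoff.
* Degenerate inputs: all-identical ANOVA data → p = 1; zero pooled SD
  with equal means → g = 0, with unequal means → error; empty strata,
  rank-deficient designs, zero-variance covariates and zero margins
  raise with the offending stratum or variable named.
* Aggregated and sex-stratified bootstrap runs use independent streams;
  composite and sex-stratified effect-size estimates likewise (whether
  the original analyses shared draws is unstated; independence is the
  conservative choice).
* Sex-stratified resampling draws n equal to the sex-stratum size, not
  the full group size.
* Chromosome enrichment: intra-chromosome pairs are legal buckets;
  pairs with zero control count are excluded from ranking (a
  `min_control` filter, default 1, guards tiny denominators); ranking
  ties break by exposed count then pair label, so output is
  deterministic under any edge-list permutation.
* All pipeline outputs are TSV/JSON with pinned float formatting; a
  manifest (seed, config hash, file list) makes two runs with one
  config byte-identical.

## Problem sizes in the test suite

The suite runs the recovery analyses at reduced but fixed sizes chosen
as the smallest that leave the assertions comfortably away from their
Monte-Carlo noise floor: B = 1000 for classification recovery
(50 seeds), B = 1000 for CI coverage (200 replicates), B = 500 for the
co-secretion pattern (25 seeds), B = 100–800 for the structural and
invariance checks. The full-scale default (B = 2000) is exercised
through the pipeline interface.

## Known limitations

* The count-exceedance test compares bootstrap count distributions
  across strata of different sizes, but with-replacement resampling
  inflates significant-pair counts more strongly at smaller n (more
  duplicate-driven spurious correlations). When the reference stratum
  is smaller than the exposed one — as for the unexposed-female T2
  cell, n = 8 — the reference mean is inflated relative to the exposed
  distribution and the test loses power exactly where the sex-specific
  pattern is expected. At effect magnitudes matching the published
  per-cell counts, the full six-cell significance pattern replicates in
  only ~30% of synthetic cohorts; single-cohort significance of each
  positive cell is, however, routinely observed. Users comparing cells
  of very unequal size should treat the test as conservative for the
  larger-baseline-inflation side.
* Percentile CIs undercover mildly at very small strata (n ≤ 10);
  coverage of a planted g₀ = 1 at n = (24, 25) is ≈ 0.93.
* The Monte Carlo Fisher mode has standard error ≈ 3·10⁻⁴ at 10⁶
  draws; third-decimal agreement with exact values is expected but not
  guaranteed.
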