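# mirnaboot

Bootstrap-resampling stability analysis of circulating miRNA qPCR
panels, with fetal-sex disaggregation.

## The problem

Maternal plasma miRNAs are candidate biomarkers for the effects of
prenatal alcohol exposure (PAE) on the fetus. Cohorts in this field are
small: three exposure groups — unexposed (UE), heavily exposed with an
apparently unaffected infant (HEua), heavily exposed with an affected
infant (HEa) — sampled at mid-pregnancy (T2) and late pregnancy (T3).
Disaggregating such groups further by fetal sex leaves strata of 7–22
subjects, where single hypothesis tests are unstable. `mirnaboot`
implements the resampling strategy used in this situation: resample
each stratum with replacement at its own size for B iterations
(default B = 2000), recompute the statistic of interest in every
iteration, and report the *stability* of the result instead of a single
p-value.

The package provides, over a samples × assays Ct matrix:

* **Preprocessing** — undetected wells imputed at the Ct = 45 sentinel,
  assays kept only if detected in ≥ 80% of samples, global-mean
  normalization ΔCt_ij = Ct_ij − mean_j(Ct_i·) (removes per-sample
  technical offsets exactly).
* **Significance-stability profiles** — the proportion of bootstrap
  iterations in which a one-way ANOVA (or an ANCOVA adjusting for
  gestational age at blood draw) across UE/HEua/HEa is significant at
  α = 0.05; a miRNA is labelled *likely alcohol-sensitive, fetal
  sex-specific* for a sex when its sex-stratified proportion strictly
  exceeds both the aggregated proportion and 0.5.
* **Effect sizes** — Hedges' g, g = J·(x̄ − ȳ)/s_p with
  J = 1 − 3/(4N − 9), as a bootstrap median with a 95% percentile CI
  (2.5/97.5 percentiles over B iterations); classification rules for
  significant effects (CI excludes 0), sex medians outside the
  composite CI, and baseline fetal-sex dimorphism within UE.
* **Co-secretion networks** — all-pairs Pearson correlation with
  two-sided t p-values, significant-pair counts, partial correlations
  controlling for gestational age, bootstrap count distributions, and
  the count-exceedance test
  p = 1 − #{iterations with exposed count > mean reference count}/B.
* **Chromosome-pair enrichment** — significant miRNA pairs mapped to
  unordered chromosome pairs and ranked by
  100·(count_exposed − count_control)/count_control.
* **Cohort statistics** — Freeman–Halton Fisher exact test for r×c
  contingency tables (exact margin-constrained enumeration, plus a
  seeded Monte Carlo mode for large tables) and tie-corrected
  Kruskal–Wallis.
* **A synthetic cohort generator** with planted ground truth (group and
  sex-specific mean shifts on the Hedges'-g scale, a latent co-secretion
  factor over an X-chromosome-enriched miRNA block, background
  co-regulation, detection dropout, gestational-age covariates) for
  recovery testing of everything above.

## Worked example

```python
import mirnaboot as mb

# a synthetic cohort with the study's group sizes and a planted
# co-secretion factor in exposed-female strata
cfg = mb.cosecretion_config(seed=7)
mat, meta, annot = mb.simulate_cohort(cfg)
expr = mb.preprocess(mat)          # impute, filter >=80%, delta-Ct

res = mb.StabilityBootstrap(
    expr, meta, time_point="T2",
    config=mb.BootstrapConfig(n_iterations=500, seed=1),
).fit()
print(res.summary())
```

prints

```
Stability bootstrap (ANOVA, T2, B=500, alpha=0.05)
  miRNAs profiled : 150
  aggregated proportion>0.5 :   21   median 0.154
  male       proportion>0.5 :    7   median 0.146
  female     proportion>0.5 :   29   median 0.223
  sex-specific    : male=4, female=25, both=1
```

Read: of 150 assays passing the expression filter, 21 are significant
in more than half of the aggregated-bootstrap iterations; 4, 25 and 1
miRNAs become stably significant only in the male-, female- or
both-sex strata — with the planted factor active in the exposed-female
cell, the female stratum dominates, as expected. The same
`expr`/`meta` pair feeds `EffectSizeBootstrap` (bootstrap Hedges' g per
miRNA with CIs) and `CorrelationNetwork` (per-cell significant-pair
counts and count-exceedance tests against UE).

The same pipeline is scriptable from the shell:

```bash
mirnaboot simulate --seed 7 --cosecretion --out cohort/
mirnaboot run-all --config pipeline.yaml
```

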