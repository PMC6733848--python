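# Methods

This note documents the models and procedures implemented in `microgrowth`,
the assumptions behind them, the synthetic cohort used to exercise them, and
the numerical choices a user should know about.

## Study design emulated

A longitudinal infant cohort with stool, anthropometry and blood sampled at
three visits (6, 12 and 18 months). The scientific questions are whether
(1) the maturity of the gut microbiota, summarised as a microbiota-for-age
Z-score (MAZ), and its alpha diversity (Shannon index) predict growth over
the following 6-month interval, and (2) whether they are associated,
concurrently or predictively, with systemic inflammation (AGP, CRP).

## Microbiota processing

Classic tab-delimited OTU tables (OTUs × samples, trailing taxonomy column)
are the input format. Processing order is fixed:

1. **Low-fraction filter** — an OTU is kept only if it reaches ≥0.1% of a
   sample's reads in ≥2 samples. Applied to raw counts, before rarefaction,
   because the filter describes table construction, not diversity
   measurement.
2. **Rarefaction** — one multivariate-hypergeometric draw per sample to
   exactly 5000 reads (numpy `Generator.multivariate_hypergeometric`);
   samples below depth are dropped and reported, not retained unrarefied.
   A single draw is used rather than averaging repeated rarefactions.
3. **Shannon index** — H = −Σ p ln p in natural-log units. The base
   matters when comparing across software (log₂ conventions exist); it is
   stated here so mismatches are detectable.

## Microbiota age and MAZ

A two-pass random-forest regression of chronological age on OTU relative
abundances: pass 1 fits on all OTUs and ranks them by permutation
importance; pass 2 refits on the top k = 25. Design choices:

* **Out-of-bag reference statistics.** The per-age-bin median and SD of
  reference microbiota age use OOB predictions. In-bag predictions are
  optimistic, which would shrink the reference SD and inflate |MAZ| for
  everyone else.
* **Age bins.** 1-month bins pooled with their smaller neighbour until each
  holds ≥20 reference children. Binning (rather than a fitted reference
  curve) keeps the median-zero identity exact: reference children's per-bin
  median MAZ is 0 by construction, which the tests assert to 1e-10.
* **Permutation importance on a subsample.** Importance is computed on at
  most 300 reference samples with 3 repeats. Only the *ranking* of OTUs is
  consumed, and rankings stabilise long before the importance values do;
  the forest itself is always fit on all reference samples. (Computing
  importance strictly on out-of-bag samples per tree would be preferable in
  principle; the ranking delivered by whole-set permutation importance on
  an OOB-scored forest is equivalent for the designed monotone signals.)
* **n_trees.** The library default for `fit_reference_model` is 1000 trees
  for stable importance rankings; the pipeline default is 200, which on the
  synthetic cohorts gives the same selected-OTU sets at a quarter of the
  cost. Both are seeded.
* MAZ is scale-free by construction: predictions depend only on relative
  abundances, so multiplying a sample's counts by any constant leaves MAZ
  unchanged (tested).

## Growth outcomes

Δz = (z_end − z_start)/days × 182.625 (one standard 6-month interval,
365.25/2 days; months are 30.4375 days throughout). Age-window exclusions
are strict inequalities: a child exactly 8.0 months old at the 6-month
visit is kept. Malnutrition flags are strict: z = −2.0 exactly is not
flagged.

**Winsorization** clamps outcomes at the 2.5th/97.5th percentiles. The
bounds are nearest-rank inclusive order statistics (numpy `method="higher"`
/ `"lower"`), not interpolated percentiles: interpolated bounds shift every
time winsorization is reapplied, so the operation would not be idempotent
at any finite n. Nearest-rank bounds differ from interpolated ones by at
most one order-statistic gap and make winsorize(winsorize(x)) == winsorize(x)
exactly. Every model is also refit on the non-winsorized outcome and both
estimates are reported side by side.

## Association models

* **Repeated-measures ANCOVA.** Interval rows are stacked (6→12 with the
  6-month predictor, 12→18 with the 12-month predictor), with baseline z,
  interval indicator and covariates. Within-child correlation across the
  two rows is handled with cluster-robust (sandwich) standard errors by
  child — the least-assumption reading of a mixed-model framework, and
  swappable behind the fitting interface. A child missing one interval
  contributes the other.
* **Decision rule.** The interaction model only decides *whether* to
  stratify (p < 0.05 two-sided); the pooled coefficient is reported from a
  separate model without the interaction, because a main effect alongside
  its interaction is not interpretable as an overall association.
* **CI/p consistency.** Intervals and p-values come from the same Wald
  construction (t-based with matching degrees of freedom), so the 95% CI
  excludes the null exactly when p < 0.05 (property-tested).
* **Collinearity pruning** drops covariates with |Spearman ρ| > 0.7 against
  the predictor; categorical covariates are screened through their level
  indicators.
* **Inflammation models** are complete-case per model; rows with
  non-positive biomarker values are excluded before the log transform.
  Back-transformed coefficients exp(β) are reported with exponentiated CIs;
  `percent_change_from_ratio` converts them to the percent wording
  ((ratio − 1) × 100).
* **Separation** in logistic fits raises an error recommending an explicit
  penalized refit; it is never applied silently. At very small n the fully
  adjusted logistic information matrix can be singular; the pipeline
  records such per-outcome failures and continues (`strict=False`), while
  direct library calls raise.

## Per-taxon scan

Counts are zero-inflated, so each OTU enters as (a) a presence indicator or
(b) three categories split at the *median positive count* — the median over
present samples only (the overall median would usually be 0 and collapse
the categories), with ties at the median assigned upward so the high class
is never empty for discrete counts. The per-OTU p-value for the
three-category encoding is the joint 2-df Wald test of both contrasts.
Filters: within-sample abundances below 0.1% are zeroed cell-wise (the
filter is phrased per sample, not per OTU), then OTUs detected in <5% of
participants are dropped. BH-FDR at q = 0.15 is applied within one family
per (outcome × encoding). Both pre-FDR (raw p < 0.05) and post-FDR flags
are emitted; note that with q = 0.15 > 0.05 a BH rejection with raw
p ∈ (0.05, 0.15] is possible in small families, so neither flag implies
the other in general.

## Synthetic cohort generator

The generator is the package's test bed: it produces data with the
statistical structure the analysis assumes, with every injected parameter
recorded for recovery testing.

* **Composition.** Per-OTU logits move linearly in age; the designated
  age-discriminatory OTUs alternate increasing/decreasing. Decreasing OTUs
  are staggered early dominants (milk-adapted-taxon analogues) and
  increasing OTUs start rare, so expected Shannon diversity rises
  monotonically over 2–28 months (≈1.9 at 6 mo to ≈2.9 at 18 mo under the
  defaults, matching the 1.6→2.9 range typical of this age span).
* **Counts.** A sample's true composition is its expected proportions
  perturbed by gamma weights (shape 1/dispersion, negative-binomial-like
  marginal overdispersion) and a per-cell Bernoulli dropout mask
  (zero-inflation 0.15), renormalised; counts are one multinomial draw at a
  log-normal library size (median 30,000 reads, log-sd 0.4). This keeps
  row sums exactly equal to drawn library sizes — which independent ZINB
  draws cannot — while marginal counts remain overdispersed and
  zero-inflated.
* **Latent maturity.** Each child-visit has a maturity score (child-level
  SD 0.8 plus visit-level SD 0.6) that shifts the microbiome 1.5 months
  along the age axis per unit. The stored `maz_true` is this score; the
  stored `shannon_true` is the entropy of the sample's realised
  composition (what rarefied Shannon estimates, minus counting noise).
* **Planted effects.** Day-normalised ΔWAZ(6→12) gains 0.03 z per maturity
  unit (the 12→18 effect defaults to 0, creating a true interval
  interaction); ln CRP at 18 months gains ln(0.64) per `shannon_true` unit.
  Baseline-z feedback (−0.2) produces regression to the mean; residual
  noise SD is 0.45 z per interval.
* **Covariates** follow means/SDs typical of rural sub-Saharan
  mother-infant cohorts
  (maternal age 25.2 ± 5.9 y, height 156.1 ± 5.7 cm, BMI 22.0 ± 2.8,
  education 3.8 ± 3.5 y, assets z −0.08 ± 1.0, HIV 11.9%, food insecurity
  38.9%, sanitary access 9.6%, vaginal delivery 94.9%); the rest use fixed
  realistic defaults (parity 1+Poisson(1.5), hemoglobin 11.2 ± 1.5 g/dL,
  tap water 30%, urban 20%, facility delivery 90%). Covariates are mutually
  independent except a configurable maternal-BMI↔assets correlation (0.3)
  that exercises the collinearity screen. Biomarkers are log-normal with
  visit-specific means giving high-AGP ≈64% and high-CRP ≈29% prevalence at
  6 months, declining with age.
* **Missingness.** Visits drop out completely at random (5% per visit); 2%
  of visits are delayed 60–120 days, feeding the age-window exclusions.
  One global seed drives named substreams (composition, visits, maturity,
  counts, outcomes, covariates, dropout) so any stage is reproducible in
  isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic taxonomic composition; covariate
dependence on outcomes (no confounding is planted, so adjusted ≈ unadjusted
here by design); informative missingness; measurement error in
anthropometry; and the strong observed Shannon–MAZ coupling. On that last
point: per-visit Shannon–MAZ correlations are positive in the synthetic
cohort (as tested) but weaker than the 0.65–0.76 reported in real infant
cohorts, because the generator's idiosyncratic count noise is large
relative to the maturity-driven diversity component.

## Problem sizes used in tests and the acceptance script

Replicate studies use cohorts of 500–650 children (the scale the default
configuration emulates) but
lighter microbiomes (30–40 OTUs) when the quantity under test — a planted
regression coefficient, an interaction rate — does not involve count
modelling; recovery runs use 150–200 replicates. The microbiota-age checks
use 150–200-child cohorts with 80–100 OTUs and 150–200 trees. These sizes
were chosen so the whole suite re-runs in a few minutes while keeping
Monte-Carlo error well below the tolerances asserted.

## Known limitations

* The repeated-measures model uses cluster-robust OLS, not a random-effects
  fit; with exactly two intervals per child the two agree closely for the
  pooled coefficient, but variance components are not estimated.
* The reference model is trained on the cohort itself (as its own healthy
  reference) in the pipeline; a user-supplied external reference is
  supported through `fit_reference_model` directly.
* Forest predictions are bounded by the training age range, so MAZ
  saturates for children far outside the reference ages.
* BH-FDR assumes independence or positive dependence across per-OTU tests;
  compositional coupling between OTUs can violate this, which is one reason
  the scan is labelled exploratory.
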