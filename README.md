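# microgrowth

Analysis pipeline relating gut-microbiota **maturity** and **diversity** to
infant **growth** and **inflammation** in a longitudinal (6/12/18-month)
cohort, with a seeded synthetic-cohort generator so every stage is testable
end to end without any data download.

The package is aimed at researchers working with infant 16S OTU count tables
alongside anthropometry (WHO z-scores) and inflammation biomarkers (AGP,
CRP), who want the full chain — OTU filtering, rarefaction, microbiota-age
modelling, interval growth models, and per-taxon scans — as reproducible,
tested code.

## The quantities at the core

**Microbiota-for-age Z-score (MAZ).** A regression forest is trained on a
healthy reference to predict chronological age from the relative abundances
of the top *k* = 25 age-discriminatory OTUs (selected by permutation
importance). A sample's predicted age is its *microbiota age* m; then

    MAZ = (m − median m_ref(age)) / SD m_ref(age)

where the reference median and SD come from out-of-bag predictions of
age-matched reference children, pooled into age bins of at least 20
children.

**Shannon diversity.** H = −Σᵢ pᵢ ln pᵢ over within-sample relative
abundances, computed on tables rarefied to 5000 reads (samples below depth
are dropped). OTUs below 0.1% relative abundance in fewer than two samples
are removed first.

**Interval growth outcomes.** For each 6-month interval, the day-normalised
change in a z-score (LAZ/WAZ/WLZ/HCZ) is

    Δz = (z_end − z_start) / days_between × 182.625

Visits past the pre-specified age windows (>8, >15, >21 months) are
excluded; values below −2.0 flag stunting/underweight/wasting/small head
circumference.

**Association models.** A two-interval repeated-measures ANCOVA regresses
Δz on the start-of-interval predictor (MAZ or Shannon) with the baseline z
and pre-specified covariates, cluster-robust by child. The interval ×
predictor interaction is tested first; per-interval cross-sectional models
are reported only when it is significant (α = 0.05). Inflammation models
are linear on ln AGP / ln CRP (coefficients back-transformed to ratios, so
0.88 reads as a 12% decrease per predictor unit) and logistic on the
high-AGP (>1.0 g/L) and high-CRP (>5.0 mg/L) indicators. Outcomes are
winsorized at the 2.5th/97.5th percentiles with a non-winsorized
sensitivity refit; covariates with |Spearman ρ| > 0.7 against the predictor
are pruned. The per-OTU scan encodes each taxon as presence/absence or
three abundance categories and applies Benjamini–Hochberg FDR at 0.15 per
(outcome × encoding) family.

## Worked example

```sh
python analysis/01_simulate_cohort.py 1   # writes results/cohort/
python analysis/02_diversity_maturity.py 1
python analysis/04_inflammation_models.py 1
```

which prints (abridged):

```
cohort: 650 children, 1857 visit records (dropout removed 93)
  6mo: n=621, true Shannon 1.80 (sd 0.30), high AGP 67%, high CRP 28%
  18mo: n=616, true Shannon 2.14 (sd 0.50), high AGP 45%, high CRP 16%
maturity model: 25 age-discriminatory OTUs, out-of-bag R^2 = 0.82, 7 reference age bins
concurrent 18-month models (ratio per unit predictor):
  shannon ->   ln_crp: ratio = 0.68 (0.58, 0.81), p = 0.000  [32% decrease]
  shannon -> high_crp: ratio = 0.54 (0.34, 0.85), p = 0.007  [46% decrease]
```

The generator plants a Shannon → ln CRP slope of ln(0.64) at 18 months; the
estimated ratio of 0.68 from one cohort realisation is that effect seen
through rarefied-count estimation noise. `analysis/03_growth_models.py` and
`analysis/05_taxa_scan.py` run the growth ANCOVA and the per-taxon FDR scan
the same way. The same stages are available as a CLI
(`microgrowth run|simulate|diversity|maz|growth|inflammation|taxa-scan`)
for user-supplied tables.

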