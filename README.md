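# csehealth

Small-area analysis of children's social exclusion risk and health outcomes.

Composite deprivation indices are a standard tool for targeting services at
the neighbourhoods where disadvantaged children live.  This package
implements, as a tested and reusable pipeline, the construction of a Child
Social Exclusion (CSE) index for small areas — 13 census-style indicators in
five domains (socio-economic, education, connectedness, housing,
health-service access) — and the analyses linking it to two child health
outcomes: age-standardised rates of potentially preventable hospitalisations
(PPH) and avoidable mortality.  It is aimed at epidemiologists and social
statisticians who want to build population-weighted small-area indices, test
index–outcome gradients, or flag areas whose outcomes deviate from what
their disadvantage predicts.

The core constructions:

- **Exponential rank transformation.** Each domain score is ranked ascending
  in risk, R = k/N, and transformed as
  `X = −23·ln(1 − R·(1 − e^(−100/23)))`, spreading the deprived tail with
  X = 100 exactly at R = 1.  The composite index is the mean of the five
  transformed domain indices.
- **Population-weighted quintiles.** Quintiles contain 20% of *children*,
  not 20% of areas: areas sorted by index descending are cut by cumulative
  child population using a midpoint rule (quintile 1 = highest risk).
- **Direct age standardisation.** Area PPH rates per 1,000 children 0–14 are
  share-weighted sums of age-group rates (0–4, 5–9, 10–14) over December
  person-years, averaged across financial years.
- **Association and residual analyses.** Population-weighted Pearson
  correlations, 5×5 quintile concordance tables with diagonal statistics,
  ANOVA / Kruskal-Wallis / Welch gradient tests, backward-stepwise
  polynomial OLS of rate on index with residuals analysed by remoteness
  (Tukey–Kramer), and Pearson chi-squares on quintile deaths-vs-survivors
  tables.

Unit-record census and health data of this kind are not redistributable, so
the package includes a synthetic-data generator (`csehealth.synthetic`) that
reproduces the assumed statistical structure — a latent disadvantage factor
loading on all indicators, log-normal child populations, five remoteness
categories, Poisson event counts with a remote-area excess — and every stage
is tested against it and against independent oracles.  See
`docs/methods.md` for the model and its limitations.

## Worked example

```sh
csehealth run-all --out run --seed 2006
```

or, stage by stage, the numbered drivers:

```sh
python analysis/01_simulate.py        # 1154 synthetic small areas
python analysis/02_build_index.py    # composite index + quintiles
python analysis/03_health_rates.py   # age-standardised PPH rates
python analysis/04_associations.py   # correlations, concordance, gradients
python analysis/05_outcome_models.py # polynomial fit, residuals, mortality
python analysis/06_published_checks.py
```

`02_build_index.py` prints, for the default seed:

```
weighted correlation between composite index and latent disadvantage: 0.927
```

i.e. the constructed composite recovers the generating disadvantage factor
(r = 0.93, child-population weighted).  `05_outcome_models.py` reports the
retained polynomial terms and the residual-by-remoteness table; in the
default simulation the Remote and Very remote categories show positive mean
residual rates — hospitalisation rates above what social-exclusion risk
alone predicts — and Tukey–Kramer separates each from all three non-remote
categories.  `06_published_checks.py` tabulates recomputed vs published
quintile-level reference values, for example:

```
          basis  chi2_recomputed  chi2_published  df      p
      cse_index            49.09            49.9   4 0.0000
  socioeconomic            31.21            31.2   4 0.0000
        housing            42.45            42.5   4 0.0000
health_services             7.06             7.1   4 0.1326
```

where all domain statistics agree within one printed unit and the composite
discrepancy (49.1 vs 49.9) is a documented artefact of the source's
pre-rounded death counts.

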