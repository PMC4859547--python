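# Methods

## The composite index

The Child Social Exclusion (CSE) index summarises, for each small area, the
risk that resident children aged 0–15 are socially excluded.  It is built
from 13 census-style indicators grouped into five domains: socio-economic
(sole-parent families, bottom-quintile household income, no parent in paid
work), education (no family member with Year 12, an area test-score ratio,
share of children developmentally vulnerable at school entry), connectedness
(no home internet, no volunteering parent, no motor vehicle), housing
(rent stress under the 30/40 rule, overcrowding) and health-service access
(GPs and dentists per 1,000 persons).

Construction proceeds in five steps.

1. **Filtering.** Areas with fewer than 30 resident children aged 0–15, or a
   non-response fraction of 0.80 or higher on any indicator, are excluded
   (both thresholds configurable; the non-response threshold is inclusive).
2. **Orientation.** Ten indicators are risk proportions and pass through
   unchanged.  The three ratios where larger means *better* conditions (GP,
   dentist and test-score ratios) are negated, so larger always means higher
   risk.  Negation is rank-preserving, and because every indicator is
   standardised before PCA the choice of inversion map (negation vs
   reciprocal) does not affect the principal-component scores.
3. **Domain scores.** Four domains are summarised by the first principal
   component of their standardised indicators (correlation-matrix PCA — the
   indicators are on incomparable scales).  Housing uses the arithmetic mean
   of its two proportions because they are only weakly correlated, which
   makes a shared first component unrepresentative.  The component sign is
   pinned by requiring positive correlation with the mean of the domain's
   *standardised* oriented indicators; this makes "higher score = higher
   risk" deterministic and invariant to positively rescaling any single
   indicator (an unstandardised anchor would not be).
4. **Exponential rank transformation.** Within each domain, areas are ranked
   ascending in risk, R = k/N ∈ (0, 1], and transformed as

       X = −23 · ln(1 − R · (1 − e^(−100/23)))

   which stretches the deprived tail and fixes X = 100 exactly at R = 1.
   Ties receive consecutive ranks in stable area-id order (not averaged
   ranks) so that R is always exactly k/N and the X = 100 boundary is exact;
   averaged ranks would be an equally defensible convention but break the
   closed-form boundary.
5. **Composite and quintiles.** The composite index is the arithmetic mean of
   the five transformed domain indices; no second rank transform is applied.
   Quintiles are child-population weighted: areas are sorted by index
   descending (ties by area id), and an area joins quintile k when the
   midpoint of its cumulative-population interval lies in ((k−1)/5, k/5] of
   the total.  Each quintile therefore holds 20% of children up to the
   atomicity of single areas: its share can deviate from 20% by at most the
   largest single-area share.  Quintile 1 is always the highest-risk (or
   highest-rate) group.

## Health outcome measures

**Hospitalisation rates.** Potentially preventable hospitalisation (PPH)
counts arrive pre-classified per area × financial year × age group (0–4,
5–9, 10–14).  Person-years for a financial year use the December population,
estimated as the mean of the adjacent June estimated resident populations.
Each year's rate is directly age-standardised — a share-weighted sum of
age-specific rates, per 1,000 children 0–14 — and the per-area rate is the
unweighted mean of the yearly standardised rates (an "average annual rate",
rather than a standardised rate of pooled counts; the two differ only
through year-to-year population drift).  The standard-population age shares
are a required input: the package ships a clearly labelled synthetic
placeholder (0.34/0.33/0.33) for simulations and tests, and analyses of real
data must supply the official shares through configuration rather than rely
on figures invented here.

**Avoidable mortality.** Deaths are too rare for per-area rates (most areas
record zero or a handful in a year), so deaths and 0–14 populations are
pooled within quintiles.  The pooled 0–14 rate is applied to each quintile's
0–15 population — the population on which the quintiles were built — to
estimate deaths on a common scale.  Homogeneity of death risk across
quintiles is tested by a Pearson chi-square on the 5 × 2 deaths/survivors
table, without continuity correction, df = 4.  Areas with no recorded deaths
are genuine zeros, not missing.

## Association and residual analyses

Correlations between index (or domain) scores and PPH rates are Pearson
coefficients weighted by each area's 0–15 child population.  Concordance
between PPH-rate quintiles and index quintiles is shown as a 5 × 5 table of
the percentage of children per cell; the diagonal is the share of children
whose two quintile ranks agree, and the diagonal-plus-adjacent share allows
a one-step discrepancy.  All statistics are computed on unrounded values;
percentages are rounded to one decimal only for display, which is why
diagonal sums recomputed from a published table's rounded cells can drift
from the published summary by 0.1–0.2 points.

Differences in mean area rates across quintiles are tested with one-way
ANOVA, complemented by Kruskal-Wallis and all ten pairwise Welch t-tests
(Welch–Satterthwaite df) because rate variances differ strongly between
quintiles.  Quintile summary statistics (mean, SD, min, max) are unweighted
over areas; population weighting enters only where stated — quintile
construction and correlations.

The index–rate relationship is fitted by OLS on raw polynomial terms of the
composite index (index, index², index³), reduced by backward stepwise
elimination at α = 0.05: the non-intercept term with the largest p ≥ α is
dropped and the model refitted until every remaining term is significant;
the intercept is always retained.  Raw (non-orthogonalised) powers keep the
coefficients on the interpretable original scale.  With an exact polynomial
relationship the residual variance is zero and t-based p-values are
undefined; terms whose contribution to the fitted values is numerically
negligible (|coefficient| · SD(term) ≤ 1e−9 · SD(y)) are then treated as
droppable, which lets the procedure recover exact generating models.

Residuals from the final model (observed − fitted rate) flag areas doing
worse or better than their social-exclusion risk predicts.  They are
summarised by the five-level remoteness classification and tested with
one-way ANOVA plus Tukey–Kramer all-pairs comparisons (the Kramer form
because category sizes are very unequal).  Areas straddling remoteness
categories take the category holding the majority of their population; ties
go to the more remote category and are logged.  Categories with fewer than
two areas are excluded from the Tukey comparisons with a warning.  The
degenerate all-zero-residual case returns F = 0 rather than NaN.

## The synthetic-data generator

No unit-record source data can be redistributed, so the generator emulates
the structure the analysis assumes:

- a latent area-disadvantage factor z ~ N(0, 1) per area, loading positively
  on all 13 indicators: proportions are logistic in (loading · z + noise)
  around indicator-specific baselines; the three access/score ratios are
  log-linear with the sign reversed (more disadvantage, less access), so
  they exercise the orientation step;
- right-skewed child populations, log-normal with median ≈ 2,000 children
  (log-mean 7.6, log-SD 1.0), floored at 1;
- five remoteness categories drawn with probabilities 0.34 / 0.24 / 0.26 /
  0.075 / 0.085, matching the published distribution of analysed areas;
- PPH counts per area-year-age-group that are Poisson with log-rate
  baseline −3.8 (≈ 22 events per 1,000 child-years) + 0.4 · z + an additive
  log-excess of 0.35 (Remote) / 0.45 (Very remote), sized so remote mean
  residuals land in the published +7–12 per 1,000 range;
- avoidable deaths per area-year that are Poisson at 23 per 100,000
  child-years (≈ 880 deaths across ~3.8 M children) scaled by
  exp(0.3 · z);
- per-indicator non-response fractions drawn Beta(1.2, 60), with config
  switches that force a stated number of areas below the population
  threshold and a subset of those additionally past the non-response
  threshold, so the exclusion rules are exercised deterministically.

June populations are held constant across years, so December interpolation
is exact and rate calibration is transparent.  Age-group populations split
the 0–14 population by the configured shares with the rounding remainder
assigned to the youngest group; the 0–14 population is 15/16 of the drawn
0–15 population.

The generator deliberately omits features of real census geography: spatial
autocorrelation between neighbouring areas, multi-factor disadvantage
(everything loads on one z), realistic non-response mechanisms, and
within-area heterogeneity.  Two consequences matter for interpreting test
results.  First, because a single factor drives all domains, every domain —
including health-service access — correlates strongly with outcomes in
simulation, unlike real data where the health-services domain is nearly
uncorrelated with hospitalisation rates.  Second, passing recovery tests
shows the pipeline correctly extracts a latent factor *when the generating
model is right*, not that the index is valid for real populations.

One calibration subtlety: the population-weighted Pearson correlation
between z and the crude rate is not monotone in the disadvantage slope over
its whole range — Pearson measures linear association while the link is
log-linear, so the correlation peaks (≈ 0.96 near slope 0.3) and declines
for extreme slopes as exp(s·z) grows skewed.  The monotonicity property is
therefore asserted over the moderate-slope regime (0–0.4) the study
occupies.

## Numerical and reproducibility choices

- All randomness flows from one `numpy` `default_rng` seed; identical
  configurations reproduce every output table byte for byte.  Forced
  exclusion fixtures are drawn last so they do not perturb upstream draws.
- The rank transform evaluates X = 100 at R = 1 to < 1e−9 by construction
  (1 − (1 − e^(−100/23)) is computed once as a constant).
- The quintile rule is order-independent under ties because ties are broken
  deterministically by area id before cumulating weight.
- Pipeline stages exchange data only through CSV files under the run
  directory; each stage writes a JSON manifest with parameter values and
  SHA-256 hashes of its inputs.  A disabled stage reuses existing outputs or
  fails naming itself; a failing stage leaves a `FAILED` marker.
- Simulation-based analyses (recovery, remote-excess separation, acceptance
  reporting) use 1,000 areas; the full-scale drivers under `analysis/` use
  1,154.  Tests that only need structure use 120–300 areas.

## Known limitations

- The five domain chi-squares recomputed from published integer death counts
  agree with the published statistics only to about one printed unit, and
  the published composite-column statistic (49.9) is not reproducible from
  its printed counts at all (direct computation gives ≈ 49.1); the source
  evidently computed on unrounded estimated deaths.  The package reports
  what the stated test produces from the stated inputs and documents the gap
  rather than adjusting either.
- Stepwise term selection at α = 0.05 retains a spurious term in roughly
  5–15% of null datasets, as expected for sequential testing without
  familywise correction; this mirrors the described procedure and is not
  corrected.
- The ICD-code classification of events, real census extraction, and
  area aggregation choices are out of scope: event counts and area tables
  arrive pre-classified.
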