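# Methods

## Outcomes and model families

Models are fitted to individual child observations rather than stratum
summaries, so that survey sampling error propagates into the fit. Four
outcomes are supported: GAM and SAM (binary; binomial family with logit
link) and WHZ and MUACZ (continuous; Gaussian family, identity link). GAM is
WHZ < −2 SD and/or bilateral oedema; SAM is WHZ < −3 SD and/or oedema, with
strict inequalities, so SAM ⇒ GAM always.

Binomial models are fitted by iteratively reweighted least squares (relative
deviance tolerance 1e-8, at most 100 iterations; statsmodels' GLM routine
behind the `fit_glm` surface); Gaussian models reduce to ordinary least
squares. AIC is −2·loglik + 2·k, where k counts the regression coefficients
plus, for Gaussian models, the residual variance (evaluated at its MLE,
RSS/n). This makes binomial and Gaussian AICs internally consistent across
all candidate specifications of the same outcome.

## Anthropometric scoring and cleaning

Z-scores use the LMS method against a reference table of (indicator, sex,
key, L, M, S) rows with linear interpolation between tabulated keys. WHZ
additionally receives the restricted adjustment used by standard scoring
software: scores inside ±3 SD are returned unchanged; outside, the score is
extended linearly in measurement units using the ±2/±3 SD cutoff values
(`SDk = M(1 + k·L·S)^{1/L}`). MUACZ never receives the adjustment.

Cleaning applies four exclusion criteria in a fixed order with
first-failure reporting: (i) incomplete minimal variable set (cluster, child
id, age + unit, sex, weight, height, oedema, MUAC); (ii) age outside 6–59
completed months (6 ≤ age < 60, with ages in days converted at 30.4375
days/month); (iii) unknown sub-county; (iv) implausible Z (|WHZ| > 5 or
|MUACZ| > 5). Z-scores are computed before criterion (iv) is judged. MUAC
unit is auto-detected: values above 30 are read as millimetres and divided
by 10 (plausible child MUAC is < 30 cm and > 30 mm). A record whose height
or age falls outside the reference range cannot be scored and is assigned
the implausible-Z code — the exclusion taxonomy has no separate
out-of-reference category and the practical effect (unusable Z) is the same.

Stratum estimates are unweighted child-level proportions and means: SMART
cluster designs are approximately self-weighting, and only point estimates
are compared downstream, so no design-based variance is computed.

## Predictor engineering

- **SPI.** Monthly precipitation totals (accumulation window 1 month; the 3-
  and 6-month rolling means applied downstream provide the longer windows,
  so stacking a 3-month SPI under a further rolling mean would
  double-smooth). For each calendar month a gamma distribution is fitted by
  maximum likelihood (location pinned at 0) to the strictly positive
  reference totals; the zero fraction q enters as a point mass, with H(0) =
  q/2 (midpoint convention, avoiding −∞ and keeping the transform
  symmetric). SPI = Φ⁻¹(q + (1−q)·G(x)). At least 20 reference values per
  calendar month are required; the synthetic rainfall archive therefore
  extends back to 1996 by default, emulating a long satellite record, while
  other series only span the study period.
- **Rolling means** are right-aligned over the previous 3 or 6 months and
  average the available values, so isolated missing months are absorbed; the
  series is first expanded to a complete monthly grid so calendar gaps count
  as missing rather than silently shrinking the window.
- **Prices** are deflated to 2015 terms with an annual sector deflator
  rebased to 2015 = 100 and applied by the calendar year of the observation,
  then smoothed with a centred window-3 running median (endpoints passed
  through). Market series attach to sub-counties by minimum haversine
  distance between market and sub-county centroid, ties broken by market id.
- **Rates.** Admissions, insecurity and vaccine doses divide by
  monthly-interpolated population (annual totals anchored at July, linear
  between anchors, constant outside) per 1,000 persons; epidemic cases per
  100,000. Both scales are configurable and affect only units.
- **Quintile encoding** of zero-heavy series (cholera, measles rates): if
  the zero fraction is ≥ 0.10, zeros form category 0 and quintile cut-points
  are computed on positive values only; cut-points are stored and reused out
  of sample with clamping to the extreme categories; duplicate cut-points
  collapse to fewer categories and are recorded.
- **Linkage** joins each eligible child to its sub-county-month predictor
  values, broadcasting county-level series to member sub-counties. Row count
  is preserved; rows with any missing predictor are flagged, not dropped —
  the fold-coverage logic consumes the flag.

## Screening, selection and forests

Univariate screening fits one single-predictor model per (predictor,
rolling-window) pair and keeps the lower-AIC window, then ranks predictors
by AIC ascending (ties alphabetical). Pairs with Spearman |ρ| ≥ 0.8
(configurable) are blocked. Forward selection walks the ranking, skipping
candidates blocked against already-included terms; continuous candidates are
tried linear and as cubic B-spline smooths and the predictor is retained
only if AIC strictly decreases.

Smooth terms are fixed-df cubic B-spline bases (df from {4, 6} by AIC),
knots at training quantiles, one basis column dropped for identifiability,
out-of-range evaluation clamped to the boundary. Fixed-df bases are
deterministic, dependency-free and AIC-comparable; penalised smoothing
parameter estimation is deliberately out of scope. Because the predictors
vary only at the stratum-month level, a smooth is offered only when the
candidate column has at least 4·df distinct values — with fewer, the basis
essentially interpolates the cell means and predicts erratically on held-out
strata (the mgcv-style "basis dimension vs unique covariate values"
concern).

Two safeguards address a hazard specific to this design: predictors vary
only at the stratum-month level, so the effective covariate sample is the
number of surveyed cells, not the number of children, while child-level AIC
keeps rewarding added terms long after the model has begun interpolating
cell means. First, `fit_glm` drops (near-)aliased design columns via pivoted
QR (relative tolerance 1e-10), zeroing their coefficients the way R's GLM
reports aliased terms — otherwise a fold refit whose held-out stratum
carried the only independent variation of a column yields a singular design
and explosive out-of-sample predictions. Second, the pipeline passes forward
selection a parameter budget of one design column per three stratum cells
(minimum 4), an events-per-cell heuristic that keeps the selected models
well-determined at desk-scale stratum counts.

Random forests (scikit-learn behind the `fit_forest` surface) use 1,000
trees and at most 5 candidate split variables per node by default, bootstrap
resampling per tree, and averaged per-tree class-1 proportions (binary) or
means (continuous). Categorical predictors enter as integer codes with an
explicit training level registry; a prediction row carrying an unseen level
raises a coverage error, the concrete mechanism by which whole survey strata
drop out of cross-validation denominators. County random effects are not
implemented: in the source analysis they predicted less well out of sample
than fixed-effects models.

## Cross-validation and metrics

Folds are individual survey strata (a sub-county × survey-month reporting
unit). For each fold the model is refitted on all other strata and the mean
per-child prediction is compared with the held-out stratum's observed
child-level mean. Per-fold seeds are SHA-256-derived from (master seed, fold
id), so parallelisation or reordering cannot change results. Folds whose
rows the trained model cannot score (missing predictor series, unseen
categorical level) or whose refit fails are excluded with a recorded reason;
evaluable + excluded = total folds always.

Metrics over evaluable folds, all equally weighted: bias = mean(predicted −
observed) in outcome units (the relative variant, bias / mean prediction, is
additionally reported since "bias relative to predictions" is ambiguous and
the signed absolute version matches how such tables are printed); MAE;
within-bound proportions (defaults ±2 %/±5 % GAM, ±1 %/±2 % SAM, ±0.10/±0.25
Z); and sensitivity at crisis thresholds (defaults ≥15 %/≥20 % GAM, ≥2 %/≥5 %
SAM, ≤−1/≤−1.25 Z) — the share of observed exceedances the model also
predicts as exceedances, undefined (not zero) when no fold exceeds the
threshold. Diagnostics: variance inflation factors per design column
(flagged above 10) and, for Gaussian fits, residual skewness/kurtosis and a
Shapiro–Wilk statistic on a seeded subsample capped at 500.

## Synthetic data generator

The generator defines the study conditions for all tests:

- **Geography**: seeded centroids in a lat 0–5° N, lon 34–41° E box; one
  sentinel market per county at a member centroid.
- **Predictors**: monthly sub-county rainfall (seasonal sinusoid ×
  sub-county baseline, archive from 1996), NDVI, market prices with 3 %/yr
  inflation, MAM/SAM admissions, insecurity events; county-level epidemic
  pulses, vaccine doses and static social indicators. The drought window
  (default Oct 2016–Dec 2018 within a 2015–2018 study period) multiplies
  rainfall by 0.55 and NDVI by 0.75 and inflates prices (×1.35), admissions
  (×1.8) and insecurity (×1.5), with mean-one multiplicative log-normal
  noise (default SD 0.15) so configured effect sizes are recovered in
  expectation.
- **True risk surface**: GAM probability = logit⁻¹(β₀ + Σβⱼ·zⱼ) on z-scored
  concurrent predictor values (defaults: intercept −1.9, NDVI −0.55,
  rainfall −0.25, price +0.35, MAM admissions +0.30, yielding GAM
  prevalences roughly 5–30 % and worse conditions during the drought). Mean
  WHZ is the unit-SD Gaussian mean solving that probability
  (μ = −2 − Φ⁻¹(p)); SAM probability Φ(−3 − μ) is then automatically below
  the GAM probability; mean MUACZ = 0.8 × mean WHZ.
- **Surveys**: per county, a seeded subset of sub-counties is surveyed at
  each scheduled month (a stratum = sub-county × month, allowing repeat
  surveys); clusters carry a Gaussian random intercept (SD 0.3) on the logit
  of GAM risk, reflecting real intra-cluster correlation; child WHZ ~
  N(μ_cluster, 1); weight is back-computed from the drawn WHZ through the
  LMS reference at the emitted (0.1 cm-rounded) height, so re-scoring
  reproduces the generating WHZ exactly. MUACZ is correlated with WHZ
  (slope 0.6, unit total SD). A corruption fraction (default 2 %) plants
  missing fields, out-of-range ages, doubled weights and unknown
  sub-counties to exercise each exclusion criterion.

Two deliberate conveniences keep ground truth exact. First, the synthetic
LMS reference uses constant L = 1 (smooth power-law/linear medians, constant
S); with L = 1 the restricted WHZ adjustment is the identity, so the
weight↔WHZ round trip holds at any |Z|; real growth-standard tables in the
same schema are drop-in replacements. Second, emitted weights are not
rounded by default (`round_weight=True` applies field precision of 0.1 kg,
which perturbs re-derived WHZ by up to ~0.06 SD); and oedema (default 2 %)
is assigned only among children already below −3 WHZ, so it never changes
GAM/SAM classification and survey prevalence converges exactly to the
surface value.

What the generator does **not** emulate: spatial autocorrelation between
sub-counties, household structure, seasonality of malnutrition beyond what
the predictor link induces, age-dependent risk, oedema independent of
wasting, and measurement error in height/weight beyond rounding. Passing
tests therefore demonstrate internal correctness and recovery of known
signals under clean conditions, not expected performance on real survey
data.

## Problem sizes and numerical choices

The bundled study sizes (test suite: 2–3 counties, 24–30 strata, ~60–120
children per stratum; acceptance run: 3 counties × 3 sub-counties, 30
strata, ~2,200 children, 1,000-tree forests) are deliberate desk-scale
choices: large enough for the known predictors to be selected and for
cross-validated metrics to be stable, small enough for a full run in
minutes on one core. Gamma fitting uses scipy's MLE with the location pinned
at zero; fitted CDF values are clipped to [1e-9, 1−1e-9] before the normal
quantile, bounding SPI at about ±6. Ties in screening break alphabetically;
market-distance ties break by id; all randomness flows from a single master
seed.

## Known limitations

- Fixed-df splines are an approximation to penalised thin-plate smooths;
  with very uneven covariate support they can still produce boundary
  artefacts.
- Quintile encoders are fitted once on the full feature table, not per
  fold; categorical coverage failures are still assessed strictly against
  each fold's training rows.
- The intercept-only Gaussian AIC convention (counting the variance
  parameter) differs from some software that drops it; comparisons are
  only ever made within this package's own AIC scale.
- No uncertainty intervals accompany the cross-validated metrics.
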