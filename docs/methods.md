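# Methods

This note documents the models, the defaults and the numerical choices in
`moodpe`, and what the synthetic-data experiments do and do not establish.

## Prediction-error construction

Expectations follow the exponential recency-weighted average
`x̄ ← x̄ + α(x − x̄)` with learning rate α = 0.1 throughout; the prediction
error on an event day is the outcome minus the expectation *entering* that
day, after which the expectation is updated. Equivalently, the expectation
after *t* events is the geometric-weight sum
`(1−α)^t p₀ + α Σ_k (1−α)^(t−1−k) O_k`; the test suite holds the recursion
to this closed form within 1e-9 over random sequences.

Choices where the procedure is underdetermined:

* **Initialization.** `p₀ = 0.5` for sports (uninformative prior over
  win/loss); for irradiance, the first observed daily mean. Both are
  configurable (`ExpectationParams.p0`), so sensitivity can be probed.
* **No burn-in trimming.** PEs are used from the first event; the earliest
  PEs carry the initialization, which washes out geometrically at rate
  1−α.
* **No-game days.** The citywide sports PE is the sum over teams that
  played; days with no games contribute 0 (an empty sum), keeping the
  regression defined on every calendar day.
* **Doubleheaders.** Two games by one team in one day are processed in
  listed order, each updating the expectation; both PEs enter that day's
  citywide sum.
* **All-zero irradiance days** yield daily DNI 0 (maximally overcast), not
  missing. Day boundaries use the local civil date on the input rows; the
  package performs no timezone arithmetic.
* Each calendar year is processed independently; expectations are not
  carried across datasets.

## Calendar nuisance design

Full indicator blocks for the seven weekdays and twelve months, individual
flags for thirteen named days (New Year's Day and Jan 2, MLK Day,
Valentine's Day, Presidents' Day, Easter Sunday, Memorial Day, July 4,
Labor Day, Columbus Day, Veterans' Day, Thanksgiving, Christmas), a
paycheck flag (1st and 15th, moved to the immediately preceding weekday
when on a weekend — which can cross a month boundary), a blizzard flag
(snow *and* mean visibility < 5 miles) and an optional hurricane-window
flag. Fixed-date holidays are flagged on their date regardless of weekday;
Easter comes from the Gregorian computus (dateutil). Individual holiday
flags are the default; a pooled single column is available
(`pooled_holidays`). Reference levels are not dropped in the design module;
the model drops Sunday and January (choice affects only how nuisance
coefficients are parameterized, not the predictors of interest).

## Panel assembly

* Coverage filter: a county is retained when ≥ 80% of calendar days have
  ≥ 100 tweets; thresholds are inclusive (the stated rule excludes "fewer
  than"), and missing county-days count as zero tweets for the filter but
  never fabricate mood values.
* Population filter: postal codes with ≥ 15,000 adult residents
  (inclusive).
* Per-capita spend: `log(sales/adult_pop + ε)` with ε = 1e-6 USD/person so
  rare zero-sales days stay finite; configurable.
* Predictors of interest enter as z-scores (sample SD), standardized once
  over the pooled modelling dataset. The PE scalers fitted on the mood
  (county-day) panel are reused for the gambling (postal-day) panel so the
  treatment has identical units in the mediator and outcome models of the
  mediation step.
* Lags: the mood/gambling row at date *d* carries the sports PE from
  *d − 1* and the sunshine PE from *d*. Dates before a series starts become
  missing rows (dropped by the model), never zeros.
* Mood joins to postal rows via the postal code's county (a
  `geography.csv` mapping table); gambling rows are restricted to postal
  codes in coverage-retained counties.
* Weights: county *total* population for the mood models, postal *adult*
  population for the gambling models.

## Mixed-effects estimation

The model is `y = Xβ + Z_msa u + Z_unit v + e` with independent random
intercepts per level and residual variance `σ²_e / w_i` under precision
weights `w_i` (populations, normalized to mean 1 so estimates are invariant
to rescaling). Estimation profiles β and σ²_e out of the REML criterion
(ML available) and optimizes the variance ratios λ_g = σ²_g/σ²_e on the
square-root scale with an L-BFGS-B bound at zero, so boundary
(zero-variance) solutions are admissible; two starts (λ = 0.25, 0.0025)
guard against local minima. Because the random-effects design is a set of
group indicators, the Woodbury identity reduces every likelihood
evaluation to fixed moment matrices (U′WU, U′WX, X′WX, …) computed once —
O(q³ + q²p) per evaluation with q random intercepts, independent of the
number of rows. A level with fewer than 2 groups must be dropped by the
caller (per-city fits drop the MSA level).

Fixed-effect p-values use the normal approximation to the Wald statistic.
R² follows Nakagawa–Schielzeth for Gaussian responses:
`R²_cond = (σ²_f + σ²_msa + σ²_unit) / (σ²_f + σ²_msa + σ²_unit + σ²_e)`
with `σ²_f = var(Xβ̂)`; the marginal version omits the random components.
Degenerate nuisance columns (constant over the modelled period, e.g. a
holiday outside the data window) are pruned before fitting; a genuinely
rank-deficient design raises an error naming the offending columns.

The engine is cross-checked in the tests against statsmodels `MixedLM`
(which does not accept precision weights — the reason the engine exists)
in the unweighted case, and against a dense-matrix GLS oracle at the
fitted variance components.

Residualization for plotting is per-county weighted OLS on the nuisance
columns; residuals are orthogonal to every nuisance regressor by
construction and the mean pairwise Pearson correlation across county
residual series is available for the cross-county coherence check.

## Mediation

Quasi-Bayesian Monte Carlo with normal approximation: draw coefficient
vectors from N(β̂, Cov(β̂)) of the mediator fit and, independently, of the
outcome fit; with linear models and no treatment×mediator interaction each
draw reduces to ACME = a·b, ADE = c′, total = a·b + c′. Point estimates
are means over draws, intervals are percentile intervals, p-values are
`2·min(P(draw<0), P(draw>0))`, and `proportion mediated = ACME/total`
(reported as a percentage; values outside [0, 100] signal inconsistent
mediation and are returned as-is). Default 10,000 draws; the seed is
recorded in the output. Only the fixed-effects portion of each mixed model
enters the simulation — random-intercept variances affect the fits'
standard errors but are not re-drawn — a stated approximation, adequate
because the mediation quantities are functions of fixed effects only in
the linear no-interaction case. The mediator (mood) enters the outcome
model *unstandardized* so its units match the mediator model's outcome;
the pipeline fits dedicated outcome models (`gambling_*_mood`) for this
purpose while the headline `gambling_mood` model keeps the z-scored mood
predictor.

## Synthetic-data generator

The generator is the package's evidence base; its defaults are the study
conditions (6 MSAs, 4 analysis counties per MSA, 365 days, 3 teams per
MSA with 82/162/16-game-like seasons, α = 0.1, β_PE→mood = 0.002 per SD,
β_mood→gambling = 0.005 per SD, direct PE→gambling paths 0.003 per SD,
paycheck effect +0.01 on log spend, mood residual SD 0.02, gambling
residual SD 0.02, nested intercept SDs 0.01/0.005). Each table draws from
a named substream of the master seed, so regenerating one table never
perturbs another.

What it emulates: Bernoulli game outcomes on a bounded drifting strength
walk with occasional ties and doubleheaders; seasonal-plus-AR(1) daily
irradiance expanded to an hourly diurnal profile with zero night hours and
per-MSA variability spanning calm to volatile regimes; county-day mood
linear in the lagged/same-day z-scored PEs with calendar effects, nested
intercepts and Gaussian noise; a tweet-count dropout process including one
deliberately under-covered county per MSA so the coverage filter has work
to do; postal-day log per-capita purchases implementing the mediation
structure, with some postal populations drawn below the 15,000 floor.

Two scale conventions make generating coefficients comparable to fitted
ones: PEs are standardized over the MSA-days the downstream panel will
model, and the mediated path uses county mood standardized over the
realized gambling-MSA county-days — so both generating betas are per-SD
quantities on (essentially) the scale the fitted models report. Residual
noise is i.i.d. across county-days and does not scale with tweet volume;
there are no city-wide daily mood shocks beyond the modelled PEs and
calendar terms, no spatial correlation beyond the nested intercepts, no
mood measurement error from finite tweet samples, and no heavy tails.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the assumed data-generating process, not
robustness of the scientific conclusions to misspecification in real data.

## Validation experiments and problem sizes

* Recursion-vs-closed-form check: 1,000 random sequences, lengths up to
  500.
* Parameter recovery: 100 end-to-end replicates at the default dimensions;
  the scored models are the sports-PE → mood fit and the *fully specified*
  gambling fit (both PEs plus standardized mood) — the mood-only gambling
  model, though faithful to the headline analysis, omits the direct PE
  paths and is therefore upward-biased by construction on data generated
  with those paths, which is a property of the design, not an estimator
  defect. Acceptance: mean estimate within 5% of truth, 95% CI coverage
  within [0.90, 0.99].
* Mediation calibration: linear Gaussian chain (a = 0.5, b = 0.4,
  c′ = 0.3) at n = 20,000 with 10,000 draws, compared to the
  product-of-coefficients closed form within 3 Monte Carlo SEs; null-path
  calibration (a = 0) over 50 replicates at n = 2,000.
* The acceptance script repeats the recovery experiment with 20 replicates
  — enough to bound the mean recovery error at the few-percent level while
  keeping the script's runtime under a minute.

## Known limitations

* Wald/normal p-values, no Satterthwaite or Kenward-Roger small-sample
  corrections; with the group counts used here (≥ 6 MSAs, tens of units)
  the approximation is standard practice.
* No autocorrelation-robust or clustered standard errors; day-to-day
  dependence beyond the modelled calendar structure is not captured.
* The mediation estimator assumes sequential ignorability; no sensitivity
  analysis is provided.
* Random intercepts only — no random slopes for the PE effects, matching
  the target analysis but limiting heterogeneity modelling.
* The per-capita log transform needs an ε for zero-sales days; results are
  insensitive to ε in populous postal codes but sparse areas would warrant
  a count model instead.
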