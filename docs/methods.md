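# Methods

`carnitrend` models drivers of population change in large terrestrial
carnivores: annual rates of abundance change, assembled from heterogeneous
trend records, are regressed on land-use, climate, governance and trait
covariates in a hierarchical Bayesian model with variable selection, and the
fitted model feeds counterfactual scenarios and socioeconomic-pathway
projections. This note records the model, its assumptions, the tunable
parameters, and the design choices that were genuinely open.

## Trend standardization

Every record is reduced to the annual instantaneous rate of change
`r` (the slope of log_e abundance on year) and its percentage equivalent
`pct = 100·(e^r − 1)`.

* **Abundance/density time series** are fitted by generalized least squares
  on the log scale with an Ornstein–Uhlenbeck residual covariance
  `σ²·exp(−θ·|tᵢ−tⱼ|)`, removing the serial dependence of consecutive
  estimates. `θ` (1/years) is profiled by maximum likelihood on a log-spaced
  grid over [1e−3, 1e3] refined by bounded scalar minimisation — robust,
  derivative-free and reproducible. As `θ→∞` the fit reduces to OLS (tested
  to 1e−10). Two-point series fall back to the two-point rate with an
  undefined standard error, since the OU model is unidentifiable there;
  records are kept, not discarded. Zero abundances are rejected rather than
  offset — silent offsets bias `r`.
* **Finite rates** `λ` give `r = ln λ`; **total percent changes** `P` over
  `T` years give `r = ln(1+P/100)/T`; **per-year change series** give the
  mean log multiplier (a population that doubles then halves has `r = 0`).

## Covariates

Sixteen covariates in four groups (traits, land-use, climate, governance;
see `carnitrend.terms`) are z-transformed with the sample (n−1) standard
deviation — the convention is fixed for exact reproducibility, and the
(mean, sd) pair is stored for raw-scale back-transformation. Time-varying
covariates are summarised over the population monitoring window, optionally
extended backwards by a 0/5/10-year lag (default 10: a 1990–2000 window
then captures 1980–2000). The climate-extreme metric counts the months per
year a monthly series exceeds its pre-industrial baseline (1901–1920) mean
plus two standard deviations; exceedance is *strictly above* (tie behaviour
is measure-zero for continuous data). Covariates are sampled within a
circular "population area" buffer; the number of sampling points
interpolates log-linearly in area between 13 and 295 — areas span orders of
magnitude, so the log scale is the natural interpolation, and the raster
sampling itself is out of scope (the module consumes per-population
summaries).

Missing covariate cells are imputed by iterative chained regression: each
incomplete column is OLS-regressed on the other (current-filled) columns to
a fixed point, and each formerly missing cell carries the prediction as its
mean with a predictive sd combining the regression's residual sd and the
prediction's spread over 20 seeded bootstrap refits. The construction is
calibrated by design — when the predictors carry no information the cell
honestly reports (column mean, column sd), which matters because the
downstream measurement-error model trusts these (mean, sd) pairs literally;
an over-confident imputer attenuates coefficients. Any imputer meeting the
calibrated (mean, sd) contract is pluggable.

## The hierarchical model

For record *i* with response `y_i` (% per year):

```
y_i ~ Normal(μ_i, σ²/w_i)                        (quantitative)
y_i ~ Normal(μ_i, σ²/w_i) truncated to (L_i,U_i) (qualitative, latent)
μ_i = α + Σ_j γ_j b_j x_ij + u_genus + u_species + u_subregion + u_country
```

* **Censoring.** Qualitative categories enter as interval-censored
  observations on deliberately overlapping intervals — Decrease (−50, 0),
  Stable (−5, 5), Increase (0, 50) % per year — acknowledging the grey area
  between categories. The likelihood is the normal mass on the interval,
  computed in log space (`log_ndtr` with reflection) so |z| ≫ 8 tails stay
  accurate; it matches adaptive quadrature to better than 1e−8.
* **Quality weights.** `w = √(min(dur,10)/10) · √(min(n_obs,10)/10) ·
  (method/3)` with method class 3 = full time-series fit, 2 = converted
  quantitative summary, 1 = qualitative/unreplicated. The functional form is
  this package's own construction to the stated criteria (short timeframe,
  few observations, less robust methods); caps and exponents are
  config-exposed. Ten years / ten observations saturate their components.
  Trend-fit standard errors, when present, fold into the record sd in
  quadrature (toggleable).
* **Measurement-error covariates.** Imputed cells are latent values with
  Normal(mean, sd) priors from the imputation; interactions are products of
  (possibly latent) parents. Because μ_i is linear in each latent cell given
  the others, their conditionals are conjugate normals.
* **Selection.** Seven core main effects are always included; nine optional
  main effects and seven interactions carry Kuo–Mallick Bernoulli inclusion
  indicators `γ_j ~ Bern(0.5)`, with excluded slopes refreshed from their
  prior. Posterior inclusion probabilities are the mean of `γ_j`.
* **Random intercepts** for genus, species-in-genus, UN sub-region and
  country-in-subregion, each with a half-Cauchy(5) sd.
* **Priors** are weakly informative on the %-per-sd scale: Normal(0, 10²)
  slopes and intercept, half-Cauchy(5) for σ and the random-intercept sds,
  inclusion probability 0.5. All are overridable in `PriorSpec`.

**Sampler.** Metropolis-within-Gibbs: truncated-normal draws for censored
latents (inverse-CDF with exponential-tail fallback), conjugate normal draws
for measurement-error latents, a joint conjugate update of the intercept and
all included slopes, collapsed Bernoulli updates for `γ` (each indicator is
flipped by the exact Bayes factor with its slope integrated out, then the
slope is redrawn from its conditional — same stationary distribution as the
uncollapsed indicator flip, but inclusion moves are not bottlenecked on
lucky prior draws under the vague slope prior), conjugate (centered)
updates per random-intercept level, and inverse-gamma-augmented draws for
the half-Cauchy variance components (slice sampling for σ when trend-fit
standard errors break conjugacy). The centered parameterization is used
because it is exactly conjugate here and mixes well (split-R̂ ≈ 1.003 at
study scale); non-centering mainly benefits gradient samplers. Chains are
seeded from a single SeedSequence, so identical inputs and seed give
identical draws. Full-scale runs use 3 chains × 150 000 iterations (50 000
burn-in, thin 10); replicate experiments scale down to 3 × 5 000 (1 000
burn-in, thin 5), which suffices for the ~25-parameter fixed-effect block.

**Reported coefficients.** Model-averaged (`γ·b`) summaries are the default
output; conditional-on-inclusion summaries are also computed. Coverage
evaluation in the recovery experiments uses the conditional-on-inclusion
intervals: the model-averaged draws place a point mass at zero, so their
quantiles describe the mixture, not the effect, and structurally undercover
whenever inclusion is equivocal.

## Diagnostics

Rank-normalized split-R̂ and bulk ESS (ArviZ) on the intercept, monitored
slopes and σ, with a warning flag at R̂ ≥ 1.1. Moran's I on residuals uses
inverse great-circle-distance weights (zero diagonal, row-standardized),
the analytic null expectation −1/(n−1), and a seeded two-sided permutation
test (999 permutations by default). Pagel's λ is estimated by maximum
likelihood on per-species mean residuals, with the Brownian covariance from
a Newick tree or — when none is supplied — a two-level genus/species
taxonomy with unit branch lengths (a synthetic stand-in that lets the
diagnostic run on simulated data); the test against λ = 0 is a
likelihood-ratio χ²₁. A star phylogeny has no off-diagonal covariance and
returns λ = 0 by convention. Posterior predictive checks simulate replicate
responses per draw (censored records simulated then categorized by the
non-overlapping ±5 partition) and compare observed quantiles and category
proportions with replicate bands. Conditional/marginal R² follow the
variance-partition definition per draw, summarised by medians.

## Scenarios and projections

Counterfactuals set a pressure's covariates to **raw-scale** zero ("no
habitat loss" means zero loss, not an average z-score), re-standardized with
the stored constants, and report the per-draw difference (counterfactual −
observed prediction) per population; random intercepts cancel in the
difference. Zero is exact where observed values already equal the scenario
values, and differences are additive across disjoint zeroed sets.

Human-development pathways specify a mean pace (Slow 1.25, Moderate 1.5,
Fast 1.75 % per year), a shared linear deceleration (−0.02 % per year per
year) and an initial index of 0.2 in 1960. The yearly change is anchored at
the period midpoint so its mean over the projection equals the pace — the
anchoring is the one free choice left by stating a mean pace and a
deceleration, and midpoint anchoring satisfies both exactly. The index
compounds discretely, `HDI(t+1) = HDI(t)(1 + ΔHD(t)/100)`, matching the
annual-percentage scale of the data (the difference from continuous
compounding is second order); parameters driving the index above 1 raise an
error. Abundance projections apply the fitted change-in-human-development
coefficient to the standardized pathway, compound from a baseline of 100,
clip at zero (local extinction is absorbing), and report the median and the
95% band implied by the coefficient's posterior — which subsumes both a
full-posterior and an interval-endpoint reading. The turning point is the
first year the median trajectory's forward difference turns non-negative
after a decline; for a monotone pathway it solves the linear pathway
equation (e.g. a 1.2 %/yr crossing under Moderate turns in
1990 + (1.5−1.2)/0.02 = 2005).

## The synthetic generator

The generator emulates the statistical structure the model assumes, with
recorded ground truth: ~1123 populations of 50 species in 25 genera across
75 countries in 17 UN sub-regions; i.i.d. standard-normal z-scale
covariates (a common-factor correlation option exists but default off — the
real data's correlation structure is not reported); quantitative rates
built as intercept + Σβ·z + nested random intercepts + quality-weighted
Normal noise; ~12.3% qualitative records whose category derives from the
latent realized rate via the non-overlapping ±5 partition (the overlap in
the observation model is a property of censoring, not of the
data-generating truth); completely-at-random missingness (no mechanism is
reported, so MCAR is the neutral choice). Abundance series are simulated as
log-linear trends plus a stationary AR(1)-sampled OU process — exactly the
covariance the trend fitter assumes, and abundances stay positive.

Defaults were fixed once, a priori: intercept −1 % per year, a single true
standardized effect of −0.44 % per year per sd on
`change_human_development`, residual sd 2.0, random-intercept sds 1.0 at
each of the four levels, missing rate 0.10, quality metadata spanning 5–30
years, 3–40 observations and method classes weighted toward full
time-series fits. These give a total rate sd of ≈3 % per year (rates mostly
within −10..10, all well inside the −75..68 observed range) and, at n = 600,
a focal-effect standard error of ≈0.11 — enough information that decisive
Kuo–Mallick inclusion of a −0.44 effect is attainable under the vague
slope prior, which a power analysis shows requires |β|/se ≳ 3.5.

What the generator does **not** emulate: heavy-tailed rate extremes (the
real data reach −75/+68%), correlated covariates (by default), informative
missingness, spatially or phylogenetically structured residuals, and real
HDI trajectories. Passing recovery tests therefore demonstrate correctness
of the inference machinery under the model's own assumptions, not
robustness to their violation.

## Problem sizes

Replicate experiments use 20 datasets of 600 populations (20% qualitative)
with 3×5 000 MCMC; the qualitative-integration comparison uses 300
quantitative + 150 censored records with main effects only and selection
disabled (so the focal posterior sd is well-defined without the selection
point mass); the analysis scripts run one 400-population dataset end to end
with 3×3 000 MCMC. These sizes are the package's own scaled-down study
conditions; the estimators and contracts are identical at full scale.

## Known limitations

* The censored likelihood assumes the reporting categories map onto the
  stated intervals; the intervals are deliberate, not estimated.
* The weight function's form is a construction to stated criteria, not a
  fitted model of record quality.
* Inclusion probabilities depend on the slope prior scale (Lindley effect):
  vaguer priors exclude weak effects more aggressively. The default 10 is
  deliberately conventional; sensitivity belongs to `PriorSpec`.
* Moran's I and Pagel's λ are diagnostics only; the model has no spatial
  field or phylogenetic GLS refit.
* Model-averaged intervals undercover equivocal effects by construction;
  use the conditional-on-inclusion summaries for effect-size coverage.
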