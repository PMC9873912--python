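# carnitrend

**What drives population change in the world's large carnivores?**
`carnitrend` is an analysis package for linking land-use, climate,
governance and socioeconomic covariates to population trends of large
terrestrial carnivores (Canidae, Felidae, Hyaenidae, Ursidae). It
implements the full inference pipeline — heterogeneous trend
standardization, a hierarchical Bayesian model that integrates qualitative
trend descriptions as interval-censored observations, Kuo–Mallick variable
selection, counterfactual scenarios and human-development-pathway abundance
projections — and validates every step on synthetic data with known ground
truth.

It is written for quantitative ecologists and biostatisticians working with
population-trend databases (abundance time series, finite rates, percent
changes, qualitative Increase/Stable/Decrease records) and
population-level covariates.

## The model

Each population's trend is standardized to the annual instantaneous rate
of change *r* (the slope of log<sub>e</sub> abundance on year; time series
are fitted by GLS with an Ornstein–Uhlenbeck residual covariance
σ²e<sup>−θ|tᵢ−tⱼ|</sup>), and reported as the annual percentage rate
*pct = 100(e^r − 1)*. Rates are modelled as

y<sub>i</sub> ~ Normal(μ<sub>i</sub>, σ²/w<sub>i</sub>),  
μ<sub>i</sub> = α + Σ<sub>j</sub> γ<sub>j</sub> b<sub>j</sub> x<sub>ij</sub> +
u<sub>genus</sub> + u<sub>species|genus</sub> + u<sub>subregion</sub> +
u<sub>country|subregion</sub>

with 16 z-transformed covariates plus 7 interactions (23 effects);
qualitative records enter through the normal probability mass on
deliberately overlapping intervals (Decrease −50..0, Stable −5..5,
Increase 0..50 % per year); w<sub>i</sub> ∈ (0,1] inflates uncertainty for
short, sparse or less robust records; imputed covariate cells are latent
with Normal(mean, sd) measurement-error priors; and γ<sub>j</sub> ∈ {0,1}
are Kuo–Mallick inclusion indicators on the optional and interaction
terms. The fitted model feeds counterfactual scenarios ("no habitat loss",
"no climate change", "no growth in human development") and projections of
abundance under decelerating human-development pathways. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic dataset with known truth (600 populations, ~12% qualitative,
one true standardized effect of −0.44 %/yr per sd on
`change_human_development`), writing tables under `results/analysis/`:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_standardize_trends.py
python analysis/03_fit_model.py
python analysis/04_diagnose_fit.py
python analysis/05_counterfactual_scenarios.py
python analysis/06_project_pathways.py
```

Output (seed-reproducible):

```
$ python analysis/03_fit_model.py
fitted 600 records (73 censored), 23 fixed-effect terms, 1002 measurement-error cells
max split-R-hat on monitored parameters: 1.003 (converged: True)
change_human_development: median -0.429 [95% CI -0.650, 0.000] vs simulated
truth -0.44; inclusion probability 0.96
highest inclusion among null terms: seminatural_conversion = 0.23

$ python analysis/05_counterfactual_scenarios.py
pooled difference in annual rate of change (%), counterfactual - observed:
  no_habitat_loss      median -0.109 [95% -0.815, +0.451]
  no_climate_change    median -0.073 [95% -0.759, +0.516]
  no_hd_growth         median +0.966 [95% +0.000, +2.140]

$ python analysis/06_project_pathways.py
Slow     pace 1.25 %/yr: abundance 100 -> 96.9 by 2020; turning point 1993 (dHD 1.19 %/yr)
Moderate pace 1.50 %/yr: abundance 100 -> 85.2 by 2020; turning point 2005 (dHD 1.20 %/yr)
Fast     pace 1.75 %/yr: abundance 100 -> 74.9 by 2020; turning point 2018 (dHD 1.19 %/yr)
```

Reading this: the model recovers the simulated human-development effect
(median −0.43 vs truth −0.44; the model-averaged CI's upper bound is the
selection point mass at 0) with a decisive inclusion probability while
pure-noise covariates stay near their prior odds; the counterfactuals
show the human-development pressure dwarfing habitat and climate (as the
simulated truth dictates); and because the effect is negative with a
decelerating pathway, projected abundance is U-shaped — populations
decline while human development changes fast and turn toward recovery
once its yearly change drops to the covariate's raw mean (≈1.2 %/yr),
earlier and after smaller declines under slower pathways.

`pipeline.run_pipeline(RunConfig(...))` (YAML-configurable) runs the same
stages programmatically with manifested, seed-reproducible artifacts.

## Layout

```
src/carnitrend/     library: synthetic, trends, covariates, model,
                    diagnostics, scenarios, experiments, pipeline, terms
analysis/           numbered study drivers (simulate -> fit -> ... -> project)
tests/              pytest suite incl. acceptance checks
scripts/acceptance.py
docs/methods.md     model, assumptions, design choices, limitations
```
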