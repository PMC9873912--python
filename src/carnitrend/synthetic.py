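"""Synthetic study datasets with recorded ground truth.

Generates complete carnivore-trend datasets that mirror the statistical
structure the hierarchical model assumes: ~1123 populations of 50
species nested in genera, located in countries nested in UN sub-regions;
sixteen z-scale covariates; quantitative annual rates of change built
from a linear predictor plus nested random intercepts and
quality-weighted residual noise; a qualitative (Increase / Stable /
Decrease) subset; and missing covariate cells.  The generator records
everything it drew (the :class:`SyntheticTruth`), so parameter-recovery
and coverage tests can compare posterior estimates against known truth.

Defaults emulate the assembled study data: 1123 populations of which
~12% are qualitative, annual rates mostly within -10 to 10% per year,
and a single non-zero standardized effect of -0.44 %/yr per sd on
``change_human_development``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from carnitrend import terms
from carnitrend.trends import AbundanceSeries

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_abundance_series",
    "categorize_trend",
    "inject_missingness",
]

RANDOM_LEVELS = ("genus", "species", "subregion", "country")


def _default_betas() -> dict[str, float]:
    return {"change_human_development": -0.44}


def _default_sd_random() -> dict[str, float]:
    return {level: 1.0 for level in RANDOM_LEVELS}


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic study dataset.

    Effects (``true_intercept``, ``true_betas``, sds) are on the response
    scale, % per year; covariate effects are per standard deviation of
    the (z-scale) covariate.  ``true_betas`` may name any of the sixteen
    covariates or any ``a:b`` interaction; unnamed terms have effect 0.
    """

    n_species: int = 50
    n_genera: int = 25
    n_countries: int = 75
    n_subregions: int = 17
    n_populations: int = 1123
    frac_qualitative: float = 0.123
    true_intercept: float = -1.0
    true_betas: dict[str, float] = field(default_factory=_default_betas)
    sd_residual: float = 2.0
    sd_random: dict[str, float] = field(default_factory=_default_sd_random)
    ou_theta: float = 0.5
    ou_sigma: float = 0.2
    missing_rate: float = 0.10
    correlated_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera > self.n_species:
            raise ValueError("n_genera must not exceed n_species")
        if self.n_subregions > self.n_countries:
            raise ValueError("n_subregions must not exceed n_countries")
        for name, p in (("frac_qualitative", self.frac_qualitative),
                        ("missing_rate", self.missing_rate)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sd_residual < 0:
            raise ValueError("sd_residual must be non-negative")
        if any(sd < 0 for sd in self.sd_random.values()):
            raise ValueError("random-intercept sds must be non-negative")
        if self.ou_theta <= 0 or self.ou_sigma < 0:
            raise ValueError("ou_theta must be > 0 and ou_sigma >= 0")
        unknown = set(self.sd_random) - set(RANDOM_LEVELS)
        if unknown:
            raise ValueError(f"unknown random-intercept levels: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Everything the generator drew, for recovery tests."""

    config: SyntheticConfig
    true_rate: np.ndarray          # realized rate per population (% / yr)
    linear_predictor: np.ndarray   # intercept + fixed effects + random intercepts
    covariates: pd.DataFrame       # realized covariates before missingness
    groups: pd.DataFrame           # population -> species/genus/country/subregion
    random_intercepts: dict[str, np.ndarray]

    def params(self) -> dict:
        d = asdict(self.config)
        return {"intercept": d["true_intercept"], "betas": d["true_betas"],
                "sd_residual": d["sd_residual"], "sd_random": d["sd_random"]}


def categorize_trend(rate_pct: float) -> str:
    """Qualitative category of a latent annual rate of change.

    Uses the non-overlapping partition at +-5 %/yr: the observation
    model's censoring intervals overlap by design, but a single latent
    rate maps to exactly one reported category.
    """
    if not math.isfinite(rate_pct):
        raise ValueError("rate must be finite")
    if rate_pct <= -5:
        return "Decrease"
    if rate_pct >= 5:
        return "Increase"
    return "Stable"


def generate_abundance_series(
    r_true: float,
    n_years: int,
    ou_theta: float = 0.5,
    ou_sigma: float = 0.2,
    start_abundance: float = 100.0,
    seed: int = 0,
    start_year: int = 2000,
    population_id: str = "sim",
) -> AbundanceSeries:
    """Simulate a log-linear abundance series with OU residuals.

    Log-abundance is ``log(start) + r_true * (year - year0)`` plus a
    stationary Gaussian process with sd ``ou_sigma`` and correlation
    ``exp(-ou_theta * dt)`` between years ``dt`` apart — the exact
    inverse of the OU-GLS trend fit.
    """
    if n_years < 2:
        raise ValueError("need at least two years")
    if ou_theta <= 0 or ou_sigma < 0 or start_abundance <= 0:
        raise ValueError("require ou_theta > 0, ou_sigma >= 0, start_abundance > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    noise = np.zeros(n_years)
    if ou_sigma > 0:
        phi = math.exp(-ou_theta)
        noise[0] = rng.normal(0.0, ou_sigma)
        innov_sd = ou_sigma * math.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, innov_sd, n_years - 1)
        for i in range(1, n_years):
            noise[i] = phi * noise[i - 1] + eps[i - 1]
    log_abund = math.log(start_abundance) + r_true * t + noise
    return AbundanceSeries(
        population_id=population_id,
        years=start_year + t,
        abundances=np.exp(log_abund),
    )


def _all_term_names() -> list[str]:
    mains = list(terms.COVARIATES)
    inter = [terms.interaction_name(a, b) for a, b in terms.DEFAULT_INTERACTIONS]
    return mains + inter


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic study dataset.

    Returns ``(trend_table, covariate_table, truth)``.  The trend table
    has one row per population with hierarchy labels, coordinates, the
    monitoring window, quality metadata and either a quantitative ``pct``
    or a qualitative ``category``.  The covariate table is complete
    (missingness is injected separately by :func:`inject_missingness`).
    Identical configs (including seed) give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_populations

    unknown = set(cfg.true_betas) - set(_all_term_names())
    if unknown:
        raise ValueError(f"unknown terms in true_betas: {sorted(unknown)}")

    # hierarchy maps (functions: each species one genus, each country one subregion)
    genus_of_species = np.arange(cfg.n_species) % cfg.n_genera
    subregion_of_country = np.arange(cfg.n_countries) % cfg.n_subregions
    species_idx = rng.integers(0, cfg.n_species, n)
    country_idx = rng.integers(0, cfg.n_countries, n)
    genus_idx = genus_of_species[species_idx]
    subregion_idx = subregion_of_country[country_idx]

    # covariates on the z scale, optionally sharing a common factor
    Z = rng.standard_normal((n, len(terms.COVARIATES)))
    if cfg.correlated_covariates:
        common = rng.standard_normal((n, 1))
        Z = (Z + 0.6 * common) / math.sqrt(1.0 + 0.36)
    cov = pd.DataFrame(Z, columns=list(terms.COVARIATES))

    # design including interactions
    X = cov.copy()
    for a, b in terms.DEFAULT_INTERACTIONS:
        X[terms.interaction_name(a, b)] = cov[a] * cov[b]
    beta = np.array([cfg.true_betas.get(t, 0.0) for t in X.columns])

    u = {
        "genus": rng.normal(0, cfg.sd_random["genus"], cfg.n_genera),
        "species": rng.normal(0, cfg.sd_random["species"], cfg.n_species),
        "subregion": rng.normal(0, cfg.sd_random["subregion"], cfg.n_subregions),
        "country": rng.normal(0, cfg.sd_random["country"], cfg.n_countries),
    }
    linpred = (
        cfg.true_intercept
        + X.to_numpy() @ beta
        + u["genus"][genus_idx]
        + u["species"][species_idx]
        + u["subregion"][subregion_idx]
        + u["country"][country_idx]
    )

    # quality metadata; residual noise is quality-weighted as in the model
    n_qual = int(math.floor(cfg.frac_qualitative * n))
    qual_mask = np.zeros(n, dtype=bool)
    if n_qual:
        qual_mask[rng.choice(n, n_qual, replace=False)] = True
    duration = rng.integers(5, 31, n).astype(float)
    n_obs = rng.integers(3, 41, n)
    method_class = rng.choice([3, 2, 1], size=n, p=[0.7, 0.2, 0.1])
    method_class[qual_mask] = 1
    n_obs[qual_mask] = np.minimum(n_obs[qual_mask], 5)
    from carnitrend.model import weight_precision, QualityMeta  # local: avoid cycle

    w = np.array([
        weight_precision(QualityMeta(duration[i], int(n_obs[i]), int(method_class[i])))
        for i in range(n)
    ])
    rate = linpred + rng.normal(0.0, 1.0, n) * cfg.sd_residual / np.sqrt(w)

    start_year = rng.integers(1970, 2016 - duration.astype(int))
    trend = pd.DataFrame({
        "population_id": [f"pop_{i:05d}" for i in range(n)],
        "species": [f"sp_{s:03d}" for s in species_idx],
        "genus": [f"gen_{g:03d}" for g in genus_idx],
        "country": [f"cty_{c:03d}" for c in country_idx],
        "subregion": [f"reg_{r:03d}" for r in subregion_idx],
        "latitude": rng.uniform(-55, 70, n).round(4),
        "longitude": rng.uniform(-180, 180, n).round(4),
        "area_km2": np.power(10.0, rng.uniform(1, 5, n)).round(2),
        "start_year": start_year,
        "end_year": start_year + duration.astype(int),
        "response_kind": np.where(qual_mask, "qualitative", "quantitative"),
        "pct": np.where(qual_mask, np.nan, rate),
        "category": [categorize_trend(rate[i]) if qual_mask[i] else "" for i in range(n)],
        "duration_years": duration,
        "n_observations": n_obs,
        "method_class": method_class,
    })

    cov_table = cov.copy()
    cov_table.insert(0, "population_id", trend["population_id"])

    truth = SyntheticTruth(
        config=cfg,
        true_rate=rate.copy(),
        linear_predictor=linpred,
        covariates=cov_table.copy(),
        groups=trend[["population_id", "species", "genus", "country", "subregion"]].copy(),
        random_intercepts=u,
    )
    return trend, cov_table, truth


def inject_missingness(
    cov_table: pd.DataFrame,
    missing_rate: float,
    seed: int,
    columns: list[str] | None = None,
    min_observed: int = 2,
) -> pd.DataFrame:
    """Blank covariate cells completely at random.

    Each eligible cell goes missing independently with probability
    ``missing_rate``; every column is guaranteed to keep at least
    ``min_observed`` observed values (cells are un-masked at random if
    needed) so downstream imputation stays well-posed.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    out = cov_table.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = columns if columns is not None else [
        c for c in out.columns if c != "population_id" and not c.endswith("__sd")
    ]
    n = len(out)
    for c in cols:
        mask = rng.random(n) < missing_rate
        n_keep = n - int(mask.sum())
        if n_keep < min_observed:
            unmask = rng.choice(np.where(mask)[0], min_observed - n_keep, replace=False)
            mask[unmask] = False
        vals = out[c].to_numpy(dtype=float).copy()
        vals[mask] = np.nan
        out[c] = vals
    return out
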