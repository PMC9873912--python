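"""Counterfactual scenarios and human-development pathway projections.

Counterfactuals ask how each observed population trend would differ had
a pressure not occurred: the scenario's covariates are set to raw-scale
zero (re-standardized with the stored z-transform constants), the fitted
model predicts each population's rate under both covariate sets, and
the per-draw difference (counterfactual minus observed prediction) is
summarized per population.  Positive differences mean populations would
have been better off without the pressure.

Pathway projections explore decelerating human-development growth: the
instantaneous change in human development declines linearly at a shared
deceleration (-0.02 %/yr per year) around a pathway-specific mean pace
(Slow 1.25, Moderate 1.5, Fast 1.75 %/yr), the human development index
compounds from 0.2 in 1960, and the fitted ``change_human_development``
coefficient maps the pathway into an abundance trajectory from a
baseline of 100, with credible bands from the coefficient's posterior.
A trajectory's turning point is the year decline flips to recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from carnitrend import terms as term_registry

__all__ = [
    "ScenarioSpec",
    "PathwayScenario",
    "ProjectionResult",
    "DEFAULT_SCENARIOS",
    "DEFAULT_PATHWAYS",
    "counterfactual_diff",
    "hd_pathway",
    "project_abundance",
    "turning_point",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual: which covariates are held at raw-scale zero."""

    name: str
    zeroed_covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.zeroed_covariates:
            raise ValueError("scenario must zero at least one covariate")


DEFAULT_SCENARIOS: dict[str, ScenarioSpec] = {
    "no_habitat_loss": ScenarioSpec("no_habitat_loss", ("primary_land_loss",)),
    "no_climate_change": ScenarioSpec(
        "no_climate_change", ("change_extreme_heat", "change_drought")),
    "no_hd_growth": ScenarioSpec("no_hd_growth", ("change_human_development",)),
}


@dataclass(frozen=True)
class PathwayScenario:
    """A decelerating human-development pathway.

    ``pace`` is the mean rate of change in human development (% per
    year) over the projection period; the yearly change declines
    linearly at ``deceleration`` (% per year per year), anchored at the
    period midpoint so its mean equals the pace.
    """

    label: str = "Moderate"
    pace: float = 1.5
    deceleration: float = -0.02
    hd0: float = 0.2
    start_year: int = 1960
    end_year: int = 2020

    def __post_init__(self) -> None:
        if self.pace <= 0:
            raise ValueError("pace must be positive")
        if not (0 < self.hd0 <= 1):
            raise ValueError("initial human development must lie in (0, 1]")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")


DEFAULT_PATHWAYS: tuple[PathwayScenario, ...] = (
    PathwayScenario("Slow", 1.25),
    PathwayScenario("Moderate", 1.5),
    PathwayScenario("Fast", 1.75),
)


@dataclass
class ProjectionResult:
    """Median abundance trajectory with 95% credible band."""

    label: str
    years: np.ndarray
    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    baseline: float


def counterfactual_diff(samples, inputs, scenario: ScenarioSpec) -> dict:
    """Per-population difference in predicted annual rate of change (%).

    For each posterior draw and population: prediction with the
    scenario covariates set to raw-scale zero minus prediction with
    observed covariates.  Random intercepts and all other covariates are
    identical in both predictions, so they cancel and only the zeroed
    main effects and interactions involving them contribute.

    Returns ``{"per_population": DataFrame, "pooled": dict}`` with
    median and 50/95% quantiles.
    """
    col_of = {t: j for j, t in enumerate(inputs.terms)}
    for name in scenario.zeroed_covariates:
        if name not in col_of:
            raise ValueError(f"scenario covariate {name!r} not in the model")
        if name not in inputs.standardization:
            raise ValueError(f"no standardization constants stored for {name!r}")

    X_obs = inputs.X
    X_cf = X_obs.copy()
    for name in scenario.zeroed_covariates:
        mean, sd = inputs.standardization[name]
        X_cf[:, col_of[name]] = (0.0 - mean) / sd
    # recompute interactions whose parents changed
    for t, j in col_of.items():
        if ":" in t:
            a, b = t.split(":")
            if a in scenario.zeroed_covariates or b in scenario.zeroed_covariates:
                X_cf[:, j] = X_cf[:, col_of[a]] * X_cf[:, col_of[b]]

    beta = samples.flat(samples.beta)              # (D, p)
    diff = beta @ (X_cf - X_obs).T                 # (D, n)
    q = np.quantile(diff, [0.025, 0.25, 0.5, 0.75, 0.975], axis=0)
    per_pop = pd.DataFrame({
        "population_id": inputs.population_ids,
        "q2.5": q[0], "q25": q[1], "median": q[2], "q75": q[3], "q97.5": q[4],
    })
    pooled_q = np.quantile(diff, [0.025, 0.25, 0.5, 0.75, 0.975])
    pooled = {"q2.5": float(pooled_q[0]), "q25": float(pooled_q[1]),
              "median": float(pooled_q[2]), "q75": float(pooled_q[3]),
              "q97.5": float(pooled_q[4])}
    return {"per_population": per_pop, "pooled": pooled, "draws": diff}


def hd_pathway(spec: PathwayScenario) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Yearly change in human development and the implied HDI trajectory.

    ``dhd(t) = pace + deceleration * (t - midpoint)`` for every year of
    the projection (midpoint anchoring: the mean of the series equals
    the pace); ``hdi(t+1) = hdi(t) * (1 + dhd(t)/100)`` from ``hd0``.
    Raises if the pathway drives the index above 1.
    """
    years = np.arange(spec.start_year, spec.end_year + 1)
    mid = 0.5 * (spec.start_year + spec.end_year)
    dhd = spec.pace + spec.deceleration * (years - mid)
    hdi = np.empty_like(dhd)
    hdi[0] = spec.hd0
    for k in range(1, years.size):
        hdi[k] = hdi[k - 1] * (1.0 + dhd[k - 1] / 100.0)
        if hdi[k] > 1.0:
            raise ValueError(f"pathway drives human development above 1 in {years[k]}")
    return years, dhd, hdi


def project_abundance(
    beta_draws,
    standardization: tuple[float, float],
    pathway: PathwayScenario,
    baseline_abundance: float = 100.0,
    other_terms: float = 0.0,
) -> ProjectionResult:
    """Project abundance under a human-development pathway.

    Per posterior draw of the ``change_human_development`` coefficient
    (``beta_draws``, % per year per sd): the predicted rate in year t is
    ``g(t) = other_terms + beta * z(dhd(t))`` with ``z`` the stored
    standardization of the covariate; abundance compounds annually as
    ``N(t+1) = N(t) * (1 + g(t)/100)`` from the baseline, clipped at 0
    (local extinction is absorbing).  All other covariates sit at their
    mean (z = 0), isolating the marginal effect.
    """
    beta = np.asarray(beta_draws, dtype=float).ravel()
    if beta.size == 0:
        raise ValueError("empty draw set")
    if baseline_abundance <= 0:
        raise ValueError("baseline abundance must be positive")
    mean, sd = standardization
    years, dhd, _ = hd_pathway(pathway)
    z = (dhd - mean) / sd
    g = other_terms + beta[:, None] * z[None, :]        # (D, T)
    growth = np.maximum(1.0 + g / 100.0, 0.0)           # clip at extinction
    traj = np.empty((beta.size, years.size))
    traj[:, 0] = baseline_abundance
    for k in range(1, years.size):
        traj[:, k] = traj[:, k - 1] * growth[:, k - 1]
    med = np.median(traj, axis=0)
    lo, hi = np.percentile(traj, [2.5, 97.5], axis=0)
    return ProjectionResult(
        label=pathway.label, years=years, median=med, lo95=lo, hi95=hi,
        baseline=baseline_abundance,
    )


def turning_point(
    result: ProjectionResult, pathway: PathwayScenario
) -> tuple[int, float] | None:
    """Year the median trajectory flips from decline to recovery.

    Returns ``(year, dhd_at_year)`` for the first year whose forward
    change is non-negative after at least one year of decline, or
    ``None`` when the trajectory never declines (or never recovers).
    """
    years, dhd, _ = hd_pathway(pathway)
    d = np.diff(result.median)
    declined = False
    for k in range(d.size):
        if d[k] < 0:
            declined = True
        elif declined and d[k] >= 0:
            return int(result.years[k]), float(dhd[k])
    return None
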