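"""Standardize heterogeneous population-trend records to annual rates.

Every supported trend datatype is converted to the annual instantaneous
rate of change ``r`` (the slope of log_e abundance on year, i.e. the
population growth rate) and its percentage equivalent
``pct = 100 * (exp(r) - 1)``.

Abundance (or density) time series are fitted by log-linear regression
with a continuous Ornstein-Uhlenbeck (OU) residual process: the error
covariance between observations in years ``t_i`` and ``t_j`` is
``sigma^2 * exp(-theta * |t_i - t_j|)``, which removes the
non-independence of consecutive abundance estimates.  ``theta`` is
estimated by profile maximum likelihood; as ``theta -> inf`` the fit
reduces to ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "AbundanceSeries",
    "TrendEstimate",
    "fit_loglinear_ou",
    "rate_from_finite_rate",
    "rate_from_percent_change",
    "rate_from_change_series",
    "pct_from_instantaneous",
]

#: Bounds for the OU mean-reversion rate (1/years) in profile likelihood.
THETA_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class AbundanceSeries:
    """A population's year-indexed abundance (or density) estimates."""

    population_id: str
    years: np.ndarray
    abundances: np.ndarray
    unit: str = "abundance"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        abund = np.asarray(self.abundances, dtype=float)
        if years.ndim != 1 or abund.ndim != 1 or years.size != abund.size:
            raise ValueError("years and abundances must be 1-D and equal length")
        if years.size < 2:
            raise ValueError("an abundance series needs at least two observations")
        if not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")
        if not np.all(np.isfinite(abund)) or np.any(abund <= 0):
            raise ValueError("abundances must be finite and strictly positive")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "abundances", abund)

    def __len__(self) -> int:
        return self.years.size


@dataclass(frozen=True)
class TrendEstimate:
    """An annual instantaneous rate of change with provenance metadata.

    ``pct`` is always ``100 * (exp(r) - 1)``; ``se_r`` is NaN when the
    source datatype carries no uncertainty (downstream weighting treats
    such records via their quality metadata instead).
    """

    r: float
    se_r: float
    n_obs: int
    duration_years: float
    method: str
    ou_theta_hat: float = math.nan
    pct: float = field(init=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise ValueError("rate estimate must be finite")
        object.__setattr__(self, "pct", pct_from_instantaneous(self.r))


def pct_from_instantaneous(r: float) -> float:
    """Convert an instantaneous rate to the annual percentage rate of change."""
    if not math.isfinite(r):
        raise ValueError("rate must be finite")
    return 100.0 * math.expm1(r)


def rate_from_finite_rate(lam: float) -> TrendEstimate:
    """Annual rate from a mean finite rate of change ``lambda`` (r = ln lambda)."""
    if not (lam > 0):
        raise ValueError("finite rate of change must be positive")
    return TrendEstimate(
        r=math.log(lam), se_r=math.nan, n_obs=1, duration_years=1.0,
        method="finite_rate",
    )


def rate_from_percent_change(total_pct: float, years: float) -> TrendEstimate:
    """Annual rate from a total percent change over ``years`` years."""
    if not (total_pct > -100):
        raise ValueError("percent change must exceed -100 (population extant)")
    if not (years > 0):
        raise ValueError("duration must be positive")
    r = math.log1p(total_pct / 100.0) / years
    return TrendEstimate(
        r=r, se_r=math.nan, n_obs=2, duration_years=float(years),
        method="percent_change",
    )


def rate_from_change_series(multipliers) -> TrendEstimate:
    """Annual rate from a series of per-year finite changes.

    E.g. a population that doubled then halved ([2, 0.5]) has mean log
    multiplier 0, hence no net trend.
    """
    mult = np.asarray(multipliers, dtype=float)
    if mult.size < 1:
        raise ValueError("change series must contain at least one multiplier")
    if np.any(~np.isfinite(mult)) or np.any(mult <= 0):
        raise ValueError("all finite-change multipliers must be positive")
    logs = np.log(mult)
    se = float(np.std(logs, ddof=1) / math.sqrt(mult.size)) if mult.size > 1 else math.nan
    return TrendEstimate(
        r=float(logs.mean()), se_r=se, n_obs=int(mult.size),
        duration_years=float(mult.size), method="change_series",
    )


def _ou_profile_negloglik(log_theta: float, t: np.ndarray, y: np.ndarray):
    """Profile negative log-likelihood of the OU-GLS regression at ``theta``.

    Slope/intercept and sigma^2 are profiled out analytically; returns
    (negloglik, slope, se_slope, sigma2).
    """
    theta = math.exp(log_theta)
    n = t.size
    corr = np.exp(-theta * np.abs(t[:, None] - t[None, :]))
    # tiny jitter guards Cholesky for near-singular correlation (theta -> 0)
    corr[np.diag_indices(n)] += 1e-10
    c, low = linalg.cho_factor(corr, lower=True)
    X = np.column_stack([np.ones(n), t])
    Xw = linalg.cho_solve((c, low), X)
    yw = linalg.cho_solve((c, low), y)
    xtx = X.T @ Xw
    xty = X.T @ yw
    coef = np.linalg.solve(xtx, xty)
    resid = y - X @ coef
    rss = float(resid @ linalg.cho_solve((c, low), resid))
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    nll = 0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    cov = np.linalg.inv(xtx)
    dof = max(n - 2, 1)
    se_slope = math.sqrt(max(cov[1, 1], 0.0) * rss / dof)
    return nll, float(coef[1]), se_slope, sigma2


def fit_loglinear_ou(series: AbundanceSeries, theta: float | None = None) -> TrendEstimate:
    """Fit ``log_e(abundance) ~ year`` with OU-correlated errors.

    Parameters
    ----------
    series
        The abundance time series (length >= 2; length 2 falls back to
        the two-point rate since the OU model is then unidentifiable).
    theta
        Optional fixed mean-reversion rate (1/years).  When ``None``
        (default), theta is estimated by profile maximum likelihood on a
        log-spaced grid over [1e-3, 1e3] refined by bounded scalar
        minimisation.

    Returns
    -------
    TrendEstimate
        The GLS slope ``r`` (per year), its standard error, and the
        estimated (or fixed) theta.
    """
    t = series.years - series.years[0]
    y = np.log(series.abundances)
    duration = float(series.years[-1] - series.years[0])
    if len(series) == 2:
        r = float((y[1] - y[0]) / (t[1] - t[0]))
        return TrendEstimate(
            r=r, se_r=math.nan, n_obs=2, duration_years=duration,
            method="abundance_series",
        )

    lo, hi = math.log(THETA_BOUNDS[0]), math.log(THETA_BOUNDS[1])
    if theta is not None:
        if not (theta > 0):
            raise ValueError("theta must be positive")
        log_theta = math.log(min(max(theta, THETA_BOUNDS[0]), THETA_BOUNDS[1]))
    else:
        grid = np.linspace(lo, hi, 25)
        nlls = [_ou_profile_negloglik(g, t, y)[0] for g in grid]
        k = int(np.argmin(nlls))
        a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda g: _ou_profile_negloglik(g, t, y)[0],
            bounds=(a, b), method="bounded",
            options={"xatol": 1e-8},
        )
        log_theta = float(res.x)

    _, slope, se_slope, _ = _ou_profile_negloglik(log_theta, t, y)
    return TrendEstimate(
        r=slope, se_r=se_slope, n_obs=len(series), duration_years=duration,
        method="abundance_series", ou_theta_hat=math.exp(log_theta),
    )
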