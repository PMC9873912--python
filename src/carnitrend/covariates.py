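"""Covariate standardization, lag windows, climate exceedance and imputation.

Covariates describing land-use, climate, governance and traits are
matched to each population over its monitoring period (optionally
extended backwards by a lag of 0, 5 or 10 years) and within a circular
"population area" buffer whose covariate sampling density follows the
buffer's size.  All covariates are z-transformed before modelling;
missing values are multiply imputed and carried forward as (mean, sd)
distributions so the model can propagate imputation uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonitoringWindow",
    "z_transform",
    "apply_lag_window",
    "exceedance_months",
    "buffer_sampling_points",
    "impute_covariates",
    "sd_columns",
]

#: Sampling-point range across the smallest and largest population areas.
MIN_POINTS, MAX_POINTS = 13, 295


@dataclass(frozen=True)
class MonitoringWindow:
    """The period (start to end year, inclusive) a population was monitored."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("monitoring window must have start_year <= end_year")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def z_transform(values) -> tuple[np.ndarray, float, float]:
    """Standardize a covariate column to mean 0, sample sd 1.

    Missing entries (NaN) are ignored when computing the mean and the
    sample (n-1) standard deviation, and stay missing in the output.
    Returns ``(standardized, mean, sd)`` so covariates can be
    back-transformed (e.g. for counterfactual zeroing on the raw scale).
    """
    x = np.asarray(values, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size < 2:
        raise ValueError("need at least two observed values to standardize")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot standardize a constant column")
    return (x - mean) / sd, mean, sd


def apply_lag_window(window: MonitoringWindow, lag_years: int) -> MonitoringWindow:
    """Extend the start of a monitoring window backwards by ``lag_years``.

    A 10-year lag turns a 1990-2000 monitoring period into 1980-2000, so
    covariates capture pressures preceding the observed abundance change.
    """
    if lag_years < 0:
        raise ValueError("lag must be non-negative")
    return MonitoringWindow(window.start_year - int(lag_years), window.end_year)


def exceedance_months(
    monthly_series: pd.DataFrame,
    baseline: MonitoringWindow,
    window: MonitoringWindow,
    value_col: str = "value",
) -> float:
    """Mean months per year a climate variable exceeds its baseline extreme.

    The threshold is the mean plus two standard deviations of the series
    over the ``baseline`` period (e.g. pre-industrial 1901-1920); the
    statistic is the number of months in the monitoring ``window``
    strictly above that threshold, divided by the window length in years.
    Applies identically to heat and drought series.
    """
    df = monthly_series
    for col in ("year", "month", value_col):
        if col not in df.columns:
            raise ValueError(f"monthly series must have a '{col}' column")
    base = df[(df["year"] >= baseline.start_year) & (df["year"] <= baseline.end_year)]
    win = df[(df["year"] >= window.start_year) & (df["year"] <= window.end_year)]
    if base.empty or win.empty:
        raise ValueError("series does not cover the baseline and/or window period")
    vals = base[value_col].to_numpy(dtype=float)
    threshold = vals.mean() + 2.0 * vals.std(ddof=1)
    n_exceed = int((win[value_col].to_numpy(dtype=float) > threshold).sum())
    return n_exceed / window.n_years


def buffer_sampling_points(area: float, area_min: float, area_max: float) -> int:
    """Number of covariate sampling points for a population-area buffer.

    Counts interpolate log-linearly in area between 13 points at the
    smallest buffer and 295 at the largest, clamped to that range:
    ``n = round(13 + 282 * (log10 a - log10 a_min) / (log10 a_max - log10 a_min))``.
    """
    if area <= 0 or area_min <= 0 or area_max <= 0:
        raise ValueError("areas must be positive")
    if area_min >= area_max:
        raise ValueError("area_min must be below area_max")
    frac = (math.log10(area) - math.log10(area_min)) / (
        math.log10(area_max) - math.log10(area_min)
    )
    n = round(MIN_POINTS + (MAX_POINTS - MIN_POINTS) * frac)
    return int(min(max(n, MIN_POINTS), MAX_POINTS))


def sd_columns(table: pd.DataFrame) -> list[str]:
    """Names of the ``<covariate>__sd`` companion columns present in a table."""
    return [c for c in table.columns if c.endswith("__sd")]


def _chained_fill(X: np.ndarray, missing: np.ndarray, n_rounds: int = 5):
    """Chained-regression fill of missing cells; returns (filled, residual sd).

    Each incomplete column is regressed (OLS) on all other columns, with
    missing predictor cells held at their current fill, iterated to a
    fixed point from a column-mean start.
    """
    n, p = X.shape
    Xf = X.copy()
    col_mean = np.nanmean(X, axis=0)
    for j in range(p):
        Xf[missing[:, j], j] = col_mean[j]
    resid_sd = np.zeros(p)
    incomplete = np.flatnonzero(missing.any(axis=0))
    ones = np.ones((n, 1))
    for _ in range(n_rounds):
        for j in incomplete:
            obs = ~missing[:, j]
            others = [k for k in range(p) if k != j]
            A = np.concatenate([ones, Xf[:, others]], axis=1)
            coef, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
            pred = A @ coef
            Xf[missing[:, j], j] = pred[missing[:, j]]
            resid = X[obs, j] - A[obs] @ coef
            dof = max(int(obs.sum()) - A.shape[1], 1)
            resid_sd[j] = math.sqrt(float(resid @ resid) / dof)
    return Xf, resid_sd


def impute_covariates(
    table: pd.DataFrame,
    seed: int,
    n_bootstrap: int = 20,
    exclude: tuple[str, ...] = ("population_id",),
) -> pd.DataFrame:
    """Impute missing covariate cells with calibrated uncertainty.

    Chained regression: each incomplete column is regressed on the other
    (current-filled) columns, iterated to a fixed point; each formerly
    missing cell receives the regression prediction as its mean.  The
    companion ``<name>__sd`` column carries the predictive standard
    deviation, combining the regression's residual sd with the
    across-refit spread of the prediction over ``n_bootstrap`` seeded
    bootstrap refits — so a cell whose predictors carry no information
    honestly reports (column mean, column sd).  Observed cells are never
    modified.
    """
    cols = [c for c in table.columns if c not in exclude and not c.endswith("__sd")]
    X = table[cols].to_numpy(dtype=float)
    missing = ~np.isfinite(X)
    out = table.copy()
    if not missing.any():
        return out
    if np.any(missing.all(axis=0)):
        bad = [cols[j] for j in np.where(missing.all(axis=0))[0]]
        raise ValueError(f"cannot impute all-missing columns: {bad}")

    n, p = X.shape
    Xf, resid_sd = _chained_fill(X, missing)

    # bootstrap the final-round regressions to measure prediction spread
    rng = np.random.default_rng(seed)
    ones = np.ones((n, 1))
    boot_preds = {j: [] for j in np.flatnonzero(missing.any(axis=0))}
    for _ in range(n_bootstrap):
        for j in boot_preds:
            obs = np.flatnonzero(~missing[:, j])
            rows = rng.choice(obs, size=obs.size, replace=True)
            others = [k for k in range(p) if k != j]
            A = np.concatenate([ones, Xf[:, others]], axis=1)
            coef, *_ = np.linalg.lstsq(A[rows], X[rows, j], rcond=None)
            boot_preds[j].append((A @ coef)[missing[:, j]])

    for j, c in enumerate(cols):
        if not missing[:, j].any():
            continue
        spread = np.std(np.stack(boot_preds[j]), axis=0, ddof=1)
        sd_cells = np.sqrt(spread ** 2 + resid_sd[j] ** 2)
        col = X[:, j].copy()
        col[missing[:, j]] = Xf[missing[:, j], j]
        out[c] = col
        sd_col = np.full(n, np.nan)
        sd_col[missing[:, j]] = np.maximum(sd_cells, 1e-6)
        out[f"{c}__sd"] = sd_col
    return out
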