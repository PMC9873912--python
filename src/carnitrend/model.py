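"""Hierarchical Bayesian model of annual population rates of change.

The response is the annual rate of change in % per year.  Quantitative
records enter through a normal likelihood; qualitative records
(Increase / Stable / Decrease) enter as interval-censored observations
whose likelihood is the normal probability mass on overlapping intervals
(-50..0, -5..5, 0..50 % per year).  Record-level error is inflated for
low-quality trends (short monitoring, few observations, less robust
methods) via a precision weight ``w`` in ``sd_i = sigma / sqrt(w_i)``.
Imputed covariate cells are latent values with normal measurement-error
priors.  The linear predictor combines an intercept, 23 fixed effects
(16 main covariates + 7 interactions) and nested random intercepts
(species in genus, country in UN sub-region).  Optional main effects and
interactions carry Kuo-Mallick Bernoulli inclusion indicators, so their
effective coefficient is ``beta_j = gamma_j * b_j`` and posterior
inclusion probabilities measure covariate support.

Posterior sampling is Metropolis-within-Gibbs with conjugate updates for
slopes, random intercepts and variance components (half-Cauchy priors
via inverse-gamma augmentation), truncated-normal draws for censored
latents, exact Bernoulli updates for inclusion indicators, and
conditional-normal draws for measurement-error covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import log_ndtr, ndtr, ndtri

from carnitrend import terms as term_registry
from carnitrend.covariates import MonitoringWindow

__all__ = [
    "QualityMeta",
    "TrendRecord",
    "PriorSpec",
    "ModelSpec",
    "McmcConfig",
    "ModelInputs",
    "PosteriorSamples",
    "DEFAULT_CENSOR_INTERVALS",
    "build_design",
    "censored_loglik",
    "weight_precision",
    "sample_posterior",
    "inclusion_probabilities",
    "predict_rate",
]

GROUP_LEVELS = ("genus", "species", "subregion", "country")

DEFAULT_CENSOR_INTERVALS: dict[str, tuple[float, float]] = {
    "Decrease": (-50.0, 0.0),
    "Stable": (-5.0, 5.0),
    "Increase": (0.0, 50.0),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityMeta:
    """Quality metadata of one trend record.

    ``method_class`` is ordinal: 3 = most robust (full time-series fit),
    2 = converted quantitative summaries, 1 = least robust (qualitative
    or unreplicated estimates).
    """

    duration_years: float
    n_observations: int
    method_class: int

    def __post_init__(self) -> None:
        if not self.duration_years > 0:
            raise ValueError("duration_years must be positive")
        if self.n_observations < 1:
            raise ValueError("n_observations must be >= 1")
        if self.method_class not in (1, 2, 3):
            raise ValueError("method_class must be 1, 2 or 3")


@dataclass(frozen=True)
class TrendRecord:
    """One population's standardized trend response plus metadata."""

    population_id: str
    species: str
    genus: str
    country: str
    subregion: str
    latitude: float
    longitude: float
    area_km2: float
    window: MonitoringWindow
    quality: QualityMeta
    pct: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        has_pct = self.pct is not None and math.isfinite(self.pct)
        has_cat = bool(self.category)
        if has_pct == has_cat:
            raise ValueError(
                f"{self.population_id}: exactly one of pct/category required"
            )
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError(f"{self.population_id}: coordinates out of range")

    @property
    def response_kind(self) -> str:
        return "qualitative" if self.category else "quantitative"


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors on the % per year (z-covariate) scale."""

    slope_sd: float = 10.0
    intercept_sd: float = 10.0
    inclusion_prob: float = 0.5
    residual_scale: float = 5.0      # half-Cauchy scale of sigma
    random_scale: float = 5.0        # half-Cauchy scale of each random-intercept sd

    def __post_init__(self) -> None:
        if min(self.slope_sd, self.intercept_sd,
               self.residual_scale, self.random_scale) <= 0:
            raise ValueError("prior scales must be positive")
        if not (0.0 < self.inclusion_prob < 1.0):
            raise ValueError("inclusion probability must lie in (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the model and how qualitative records are censored."""

    core_terms: tuple[str, ...] = term_registry.CORE_TERMS
    optional_terms: tuple[str, ...] = term_registry.OPTIONAL_TERMS
    interaction_terms: tuple[tuple[str, str], ...] = term_registry.DEFAULT_INTERACTIONS
    censor_intervals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CENSOR_INTERVALS)
    )
    lag_years: int = 10
    priors: PriorSpec = PriorSpec()
    fold_se: bool = True  # fold trend-fit standard errors into record sds
    pinned_terms: tuple[str, ...] = ()  # selection-group terms with gamma fixed at 1

    def __post_init__(self) -> None:
        overlap = set(self.core_terms) & set(self.optional_terms)
        if overlap:
            raise ValueError(f"terms cannot be both core and optional: {overlap}")
        mains = set(self.core_terms) | set(self.optional_terms)
        for a, b in self.interaction_terms:
            if a not in mains or b not in mains:
                raise ValueError(f"interaction parents must be main effects: {(a, b)}")
        bad_pins = set(self.pinned_terms) - set(self.term_names)
        if bad_pins:
            raise ValueError(f"pinned terms not in the model: {sorted(bad_pins)}")
        for cat, (lo, up) in self.censor_intervals.items():
            if not lo < up:
                raise ValueError(f"censor interval for {cat} must have lower < upper")
        if self.lag_years not in (0, 5, 10):
            raise ValueError("lag_years must be one of 0, 5, 10")

    @property
    def term_names(self) -> list[str]:
        return (
            list(self.core_terms)
            + list(self.optional_terms)
            + [term_registry.interaction_name(a, b) for a, b in self.interaction_terms]
        )

    @property
    def selectable(self) -> np.ndarray:
        n_core = len(self.core_terms)
        mask = np.ones(len(self.term_names), dtype=bool)
        mask[:n_core] = False
        return mask


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iterations: int = 150_000
    n_burnin: int = 50_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.n_burnin < self.n_iterations):
            raise ValueError("n_burnin must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class _MeColumn:
    """Latent measurement-error cells of one design column."""

    col: int                      # main-effect column index in X
    rows: np.ndarray              # record rows with imputed cells
    mean: np.ndarray              # imputation means (z scale)
    sd: np.ndarray                # imputation sds (> 0)
    partners: list[tuple[int, int]]  # (interaction column, other-parent column)


@dataclass
class ModelInputs:
    """Design arrays produced by :func:`build_design`."""

    y: np.ndarray
    is_censored: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    X: np.ndarray
    terms: list[str]
    selectable: np.ndarray
    w: np.ndarray
    se_pct: np.ndarray
    group_idx: dict[str, np.ndarray]
    group_labels: dict[str, list[str]]
    me_columns: list[_MeColumn]
    standardization: dict[str, tuple[float, float]]
    spec: ModelSpec
    population_ids: list[str]
    latitude: np.ndarray | None = None
    longitude: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_terms(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def weight_precision(quality: QualityMeta) -> float:
    """Precision weight in (0, 1] from quality metadata.

    ``w = sqrt(min(d, 10)/10) * sqrt(min(n, 10)/10) * (method/3)``; the
    record-level residual sd is ``sigma / sqrt(w)``, so short, sparse or
    less robust records carry inflated uncertainty.  Ten years of
    monitoring / ten observations saturate their components.
    """
    d = math.sqrt(min(quality.duration_years, 10.0) / 10.0)
    k = math.sqrt(min(quality.n_observations, 10) / 10.0)
    return d * k * (quality.method_class / 3.0)


def censored_loglik(mu: float, sigma: float, interval: tuple[float, float]) -> float:
    """Log-probability that a Normal(mu, sigma) response lies in ``interval``.

    ``ln[Phi((U-mu)/sigma) - Phi((L-mu)/sigma)]``, computed in log space
    so extreme tails (|z| >> 8) stay finite and accurate.
    """
    lo, up = interval
    if not lo < up:
        raise ValueError("interval must have lower < upper")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    a = (lo - mu) / sigma
    b = (up - mu) / sigma
    if a > 0:  # reflect so the larger CDF value is well-conditioned
        a, b = -b, -a
    la, lb = log_ndtr(a), log_ndtr(b)
    diff = la - lb
    if diff >= 0:  # numerically empty interval
        return -math.inf
    return float(lb + math.log1p(-math.exp(diff)))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _records_to_frame(records: Sequence[TrendRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "population_id": r.population_id, "species": r.species,
            "genus": r.genus, "country": r.country, "subregion": r.subregion,
            "latitude": r.latitude, "longitude": r.longitude,
            "area_km2": r.area_km2,
            "start_year": r.window.start_year, "end_year": r.window.end_year,
            "response_kind": r.response_kind,
            "pct": np.nan if r.pct is None else r.pct,
            "category": r.category or "",
            "duration_years": r.quality.duration_years,
            "n_observations": r.quality.n_observations,
            "method_class": r.quality.method_class,
        })
    return pd.DataFrame(rows)


def build_design(
    records,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> ModelInputs:
    """Assemble response, design matrix and grouping indices.

    ``records`` is the trend table (DataFrame, or a list of
    :class:`TrendRecord`); ``covariates`` is the wide covariate table on
    the z scale, with optional ``<name>__sd`` companion columns marking
    imputed (measurement-error) cells.  Interaction columns are products
    of parent columns (imputed cells enter at their mean; the sampler
    treats them as latent).  ``standardization`` maps covariate name to
    the raw-scale (mean, sd) used for z-transforming, needed by the
    counterfactual scenarios; it defaults to (0, 1) per covariate.
    """
    spec = spec or ModelSpec()
    trend = records if isinstance(records, pd.DataFrame) else _records_to_frame(records)

    cov = covariates.set_index("population_id")
    missing_ids = [p for p in trend["population_id"] if p not in cov.index]
    if missing_ids:
        raise ValueError(f"no covariate row for populations: {missing_ids[:5]}...")
    cov = cov.loc[trend["population_id"]].reset_index()

    mains = list(spec.core_terms) + list(spec.optional_terms)
    for name in mains:
        if name not in cov.columns:
            raise ValueError(f"unknown covariate name: {name}")

    n = len(trend)
    names = spec.term_names
    col_of = {name: j for j, name in enumerate(names)}

    # main-effect columns; imputed cells enter at their mean
    X = np.empty((n, len(names)))
    me_cols: list[_MeColumn] = []
    for name in mains:
        x = cov[name].to_numpy(dtype=float)
        sd_name = f"{name}__sd"
        if sd_name in cov.columns:
            sd = cov[sd_name].to_numpy(dtype=float)
            rows = np.flatnonzero(np.isfinite(sd) & (sd > 0))
            if rows.size:
                me_cols.append(_MeColumn(
                    col=col_of[name], rows=rows,
                    mean=x[rows].copy(), sd=sd[rows].copy(), partners=[],
                ))
        if np.any(~np.isfinite(x)):
            raise ValueError(f"covariate {name} has missing values without an "
                             f"imputation sd column; impute first")
        X[:, col_of[name]] = x
    for a, b in spec.interaction_terms:
        j = col_of[term_registry.interaction_name(a, b)]
        X[:, j] = X[:, col_of[a]] * X[:, col_of[b]]
        for parent, other in ((a, b), (b, a)):
            for mc in me_cols:
                if mc.col == col_of[parent]:
                    mc.partners.append((j, col_of[other]))

    # response with censor flags
    y = trend["pct"].to_numpy(dtype=float)
    kind = trend["response_kind"].to_numpy()
    is_cens = kind == "qualitative"
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    for i in np.flatnonzero(is_cens):
        cat = trend["category"].iloc[i]
        if cat not in spec.censor_intervals:
            raise ValueError(f"row {i}: unknown category {cat!r}")
        lower[i], upper[i] = spec.censor_intervals[cat]
    if np.any(~np.isfinite(y[~is_cens])):
        raise ValueError("quantitative records must have finite pct")

    w = np.array([
        weight_precision(QualityMeta(
            float(trend["duration_years"].iloc[i]),
            int(trend["n_observations"].iloc[i]),
            int(trend["method_class"].iloc[i]),
        ))
        for i in range(n)
    ])
    if spec.fold_se and "se_pct" in trend.columns:
        se = trend["se_pct"].to_numpy(dtype=float)
        se = np.where(np.isfinite(se), se, 0.0)
    else:
        se = np.zeros(n)

    group_idx, group_labels = {}, {}
    for level in GROUP_LEVELS:
        codes, labels = pd.factorize(trend[level])
        group_idx[level] = codes.astype(np.int64)
        group_labels[level] = list(labels)

    std = {name: (0.0, 1.0) for name in mains}
    if standardization:
        std.update(standardization)

    return ModelInputs(
        y=y, is_censored=is_cens, lower=lower, upper=upper, X=X,
        terms=names, selectable=spec.selectable, w=w, se_pct=se,
        group_idx=group_idx, group_labels=group_labels, me_columns=me_cols,
        standardization=std, spec=spec,
        population_ids=list(trend["population_id"]),
        latitude=trend["latitude"].to_numpy(dtype=float) if "latitude" in trend else None,
        longitude=trend["longitude"].to_numpy(dtype=float) if "longitude" in trend else None,
    )


# ---------------------------------------------------------------------------
# posterior samples container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """MCMC draws indexed by (chain, draw) after burn-in and thinning."""

    terms: list[str]
    selectable: np.ndarray
    alpha: np.ndarray                 # (C, S)
    b: np.ndarray                     # (C, S, p) raw slopes
    gamma: np.ndarray                 # (C, S, p) inclusion indicators (core = 1)
    sigma: np.ndarray                 # (C, S)
    tau: dict[str, np.ndarray]        # level -> (C, S)
    u: dict[str, np.ndarray]          # level -> (C, S, L)
    group_labels: dict[str, list[str]]
    seed: int
    converged: bool | None = None
    max_rhat: float | None = None

    @property
    def beta(self) -> np.ndarray:
        """Effective (model-averaged) coefficients gamma_j * b_j."""
        return self.gamma * self.b

    @property
    def n_draws_total(self) -> int:
        return self.alpha.size

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Merge chain and draw axes."""
        return arr.reshape(-1, *arr.shape[2:])

    def summary(self) -> pd.DataFrame:
        """Median and 50/80/95% intervals of intercept, betas and sds."""
        rows = []

        def add(name, draws):
            q = np.quantile(draws, [0.025, 0.1, 0.25, 0.5, 0.75, 0.9, 0.975])
            rows.append({"parameter": name, "q2.5": q[0], "q10": q[1],
                         "q25": q[2], "median": q[3], "q75": q[4],
                         "q90": q[5], "q97.5": q[6]})

        add("intercept", self.alpha.ravel())
        beta = self.flat(self.beta)
        for j, t in enumerate(self.terms):
            add(t, beta[:, j])
        add("sigma", self.sigma.ravel())
        for level, t in self.tau.items():
            add(f"sd_{level}", t.ravel())
        return pd.DataFrame(rows)

    # -- persistence (long CSV of draws + JSON metadata) -------------------

    def save(self, prefix) -> None:
        """Write draws as a long CSV (chain, draw, parameter, value) plus a
        ``<prefix>.meta.json`` with term order, selection mask and labels."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        C, S = self.alpha.shape
        frames = [pd.DataFrame({"parameter": "alpha",
                                "value": self.alpha.ravel()})]
        for j, t in enumerate(self.terms):
            frames.append(pd.DataFrame({"parameter": f"b:{t}",
                                        "value": self.b[:, :, j].ravel()}))
            frames.append(pd.DataFrame({"parameter": f"gamma:{t}",
                                        "value": self.gamma[:, :, j].ravel()}))
        frames.append(pd.DataFrame({"parameter": "sigma",
                                    "value": self.sigma.ravel()}))
        for level in self.tau:
            frames.append(pd.DataFrame({"parameter": f"tau:{level}",
                                        "value": self.tau[level].ravel()}))
            for k, lab in enumerate(self.group_labels[level]):
                frames.append(pd.DataFrame({"parameter": f"u:{level}:{lab}",
                                            "value": self.u[level][:, :, k].ravel()}))
        chain = np.repeat(np.arange(C), S)
        draw = np.tile(np.arange(S), C)
        long = pd.concat(frames, ignore_index=True)
        reps = len(long) // (C * S)
        long.insert(0, "draw", np.tile(draw, reps))
        long.insert(0, "chain", np.tile(chain, reps))
        long.to_csv(prefix.with_suffix(".csv"), index=False)
        meta = {"terms": self.terms, "selectable": self.selectable.tolist(),
                "group_labels": self.group_labels, "seed": self.seed,
                "n_chains": C, "n_draws": S,
                "converged": self.converged, "max_rhat": self.max_rhat}
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, prefix) -> "PosteriorSamples":
        import json
        from pathlib import Path

        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        long = pd.read_csv(prefix.with_suffix(".csv"),
                           float_precision="round_trip")
        C, S = meta["n_chains"], meta["n_draws"]

        def grab(name):
            vals = long.loc[long["parameter"] == name, "value"].to_numpy()
            return vals.reshape(C, S)

        terms = list(meta["terms"])
        p = len(terms)
        b = np.stack([grab(f"b:{t}") for t in terms], axis=-1)
        gamma = np.stack([grab(f"gamma:{t}") for t in terms], axis=-1)
        tau = {lvl: grab(f"tau:{lvl}") for lvl in meta["group_labels"]}
        u = {lvl: np.stack([grab(f"u:{lvl}:{lab}") for lab in labs], axis=-1)
             for lvl, labs in meta["group_labels"].items()}
        return cls(
            terms=terms, selectable=np.asarray(meta["selectable"], bool),
            alpha=grab("alpha"), b=b, gamma=gamma, sigma=grab("sigma"),
            tau=tau, u=u, group_labels=meta["group_labels"], seed=meta["seed"],
            converged=meta.get("converged"), max_rhat=meta.get("max_rhat"),
        )


def inclusion_probabilities(
    samples: PosteriorSamples, term: str | None = None
) -> dict[str, float] | float:
    """Posterior inclusion probability (mean gamma) per selectable term."""
    sel = {t: float(samples.flat(samples.gamma)[:, j].mean())
           for j, t in enumerate(samples.terms) if samples.selectable[j]}
    if term is None:
        return sel
    if term not in sel:
        raise ValueError(f"term {term!r} is not under selection")
    return sel[term]


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def _sample_truncnorm(rng, mu, sd, lo, up):
    """Vectorized truncated-normal draws via inverse-CDF, tail-safe."""
    a = (lo - mu) / sd
    b = (up - mu) / sd
    ua, ub = ndtr(a), ndtr(b)
    span = ub - ua
    out = np.empty_like(mu)
    ok = span > 1e-12
    if np.any(ok):
        u = ua[ok] + rng.random(int(ok.sum())) * span[ok]
        z = ndtri(np.clip(u, 1e-15, 1 - 1e-15))
        out[ok] = mu[ok] + sd[ok] * np.clip(z, a[ok], b[ok])
    if np.any(~ok):
        # interval mass numerically vanishes: sample the tail boundary side
        idx = np.flatnonzero(~ok)
        za = a[idx]
        zb = b[idx]
        # exponential-tail approximation anchored at the nearer boundary
        lam = np.maximum(np.abs(np.where(za > 0, za, zb)), 1.0)
        e = rng.exponential(1.0 / lam)
        z = np.where(za > 0, za + e, zb - e)
        z = np.clip(z, za, zb)
        out[idx] = mu[idx] + sd[idx] * z
    return out


def _run_chain(inputs: ModelInputs, priors: PriorSpec, mcmc: McmcConfig,
               rng: np.random.Generator, store: dict, chain: int) -> None:
    n = inputs.n
    p = inputs.n_terms
    X = inputs.X.copy()
    y = inputs.y.copy()
    cens = inputs.is_censored
    idx_cens = np.flatnonzero(cens)
    w = inputs.w
    se2 = inputs.se_pct ** 2
    has_se = bool(np.any(se2 > 0))
    pinned = set(inputs.spec.pinned_terms) if inputs.spec else set()
    sel_idx = np.array([
        j for j in np.flatnonzero(inputs.selectable)
        if inputs.terms[j] not in pinned
    ], dtype=int)
    levels = list(inputs.group_idx)
    n_levels = {f: len(inputs.group_labels[f]) for f in levels}

    A_res = priors.residual_scale
    A_ran = priors.random_scale
    prior_prec_slope = 1.0 / priors.slope_sd ** 2
    prior_prec_int = 1.0 / priors.intercept_sd ** 2
    logit_pi = math.log(priors.inclusion_prob / (1 - priors.inclusion_prob))

    # --- initial state ---------------------------------------------------
    alpha = float(np.nanmean(y)) if np.any(~cens) else 0.0
    b = np.zeros(p)
    gamma = np.ones(p)
    sigma2 = float(np.nanvar(y[~cens])) if np.any(~cens) else 25.0
    sigma2 = max(sigma2, 1e-2)
    a_sig = 1.0
    tau2 = {f: 1.0 for f in levels}
    a_tau = {f: 1.0 for f in levels}
    u = {f: np.zeros(n_levels[f]) for f in levels}
    if idx_cens.size:
        y[idx_cens] = 0.5 * (inputs.lower[idx_cens] + inputs.upper[idx_cens])

    beta = gamma * b
    mu = alpha + X @ beta
    for f in levels:
        mu += u[f][inputs.group_idx[f]]

    ones = np.ones(n)
    n_keep = mcmc.n_draws
    keep = 0

    for it in range(mcmc.n_iterations):
        sd_rec = np.sqrt(sigma2 / w + se2)
        prec_rec = 1.0 / sd_rec ** 2

        # 1. latent censored responses
        if idx_cens.size:
            y[idx_cens] = _sample_truncnorm(
                rng, mu[idx_cens], sd_rec[idx_cens],
                inputs.lower[idx_cens], inputs.upper[idx_cens],
            )

        # 2. latent measurement-error covariates (linear in each latent)
        for mc in inputs.me_columns:
            r_ = mc.rows
            d = np.full(r_.size, beta[mc.col])
            for inter_col, other_col in mc.partners:
                d += beta[inter_col] * X[r_, other_col]
            x_old = X[r_, mc.col]
            c = mu[r_] - d * x_old
            prec = 1.0 / mc.sd ** 2 + d * d * prec_rec[r_]
            mean = (mc.mean / mc.sd ** 2 + d * prec_rec[r_] * (y[r_] - c)) / prec
            x_new = mean + rng.standard_normal(r_.size) / np.sqrt(prec)
            X[r_, mc.col] = x_new
            for inter_col, other_col in mc.partners:
                X[r_, inter_col] = x_new * X[r_, other_col]
            mu[r_] = c + d * x_new

        # 3. inclusion indicators, collapsed over the slope: gamma_j is
        # flipped by the exact Bayes factor with b_j integrated out, then
        # b_j is redrawn from its conditional.  Stationary distribution is
        # identical to the uncollapsed Kuo-Mallick flip, but inclusion
        # moves are not bottlenecked on lucky prior draws of b_j.
        if sel_idx.size:
            unif = rng.random(sel_idx.size)
            norm = rng.standard_normal(sel_idx.size)
            for k, j in enumerate(sel_idx):
                x = X[:, j]
                e0 = y - mu
                if gamma[j] > 0.5:
                    e0 = e0 + x * b[j]
                    mu = mu - x * b[j]
                sxx = float(prec_rec @ (x * x))
                sxy = float(prec_rec @ (x * e0))
                post_prec = prior_prec_slope + sxx
                log_bf = (0.5 * math.log(prior_prec_slope / post_prec)
                          + 0.5 * sxy * sxy / post_prec)
                logit = logit_pi + log_bf
                p_incl = (1.0 / (1.0 + math.exp(-logit))
                          if abs(logit) < 500 else float(logit > 0))
                if unif[k] < p_incl:
                    gamma[j] = 1.0
                    b[j] = sxy / post_prec + norm[k] / math.sqrt(post_prec)
                    mu = mu + x * b[j]
                else:
                    gamma[j] = 0.0
                    b[j] = norm[k] * priors.slope_sd
                beta[j] = gamma[j] * b[j]

        # 4. joint conjugate update of intercept + included slopes
        zu = mu - alpha - X @ beta  # summed random-intercept contribution
        resid_target = y - zu
        incl = np.flatnonzero(gamma > 0.5)
        D = np.concatenate([ones[:, None], X[:, incl]], axis=1)
        Wd = D * prec_rec[:, None]
        P = D.T @ Wd
        diag_prior = np.concatenate([[prior_prec_int],
                                     np.full(incl.size, prior_prec_slope)])
        P[np.diag_indices_from(P)] += diag_prior
        rhs = Wd.T @ resid_target
        cf = linalg.cho_factor(P, lower=True)
        mean_vec = linalg.cho_solve(cf, rhs)
        z = rng.standard_normal(mean_vec.size)
        draw = mean_vec + linalg.solve_triangular(cf[0].T, z, lower=False)
        alpha = float(draw[0])
        b[incl] = draw[1:]
        excl = np.flatnonzero(gamma <= 0.5)
        if excl.size:
            b[excl] = rng.standard_normal(excl.size) * priors.slope_sd
        beta = gamma * b
        mu = alpha + X @ beta + zu

        # 5. nested random intercepts
        for f in levels:
            gi = inputs.group_idx[f]
            r_f = y - mu + u[f][gi]
            sum_w = np.bincount(gi, weights=prec_rec, minlength=n_levels[f])
            sum_wr = np.bincount(gi, weights=prec_rec * r_f, minlength=n_levels[f])
            prec = sum_w + 1.0 / tau2[f]
            mean = sum_wr / prec
            u_new = mean + rng.standard_normal(n_levels[f]) / np.sqrt(prec)
            mu += (u_new - u[f])[gi]
            u[f] = u_new

        # 6. random-intercept sds (half-Cauchy via inverse-gamma mixture)
        for f in levels:
            ssq = float(u[f] @ u[f])
            tau2[f] = 1.0 / rng.gamma((n_levels[f] + 1) / 2.0,
                                      1.0 / (1.0 / a_tau[f] + ssq / 2.0))
            a_tau[f] = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A_ran ** 2 + 1.0 / tau2[f]))

        # 7. residual sd
        e = y - mu
        if not has_se:
            ssq = float((w * e) @ e)
            sigma2 = 1.0 / rng.gamma((n + 1) / 2.0,
                                     1.0 / (1.0 / a_sig + ssq / 2.0))
            a_sig = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A_res ** 2 + 1.0 / sigma2))
        else:
            sigma2 = _slice_sigma2(rng, sigma2, e, w, se2, A_res)

        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0 and keep < n_keep:
            store["alpha"][chain, keep] = alpha
            store["b"][chain, keep] = b
            store["gamma"][chain, keep] = gamma
            store["sigma"][chain, keep] = math.sqrt(sigma2)
            for f in levels:
                store["tau"][f][chain, keep] = math.sqrt(tau2[f])
                store["u"][f][chain, keep] = u[f]
            keep += 1


def _slice_sigma2(rng, sigma2, e, w, se2, scale):
    """Slice sampler for log sigma^2 when trend-fit ses break conjugacy."""

    def logpost(ls2):
        s2 = math.exp(ls2)
        v = s2 / w + se2
        ll = -0.5 * float(np.sum(np.log(v) + e * e / v))
        sig = math.sqrt(s2)
        # half-Cauchy prior on sigma, Jacobian d sigma / d log sigma^2
        lp = -math.log1p((sig / scale) ** 2) + 0.5 * ls2
        return ll + lp

    x0 = math.log(sigma2)
    y0 = logpost(x0) - rng.exponential(1.0)
    lo, hi = x0 - 1.0, x0 + 1.0
    for _ in range(20):
        if logpost(lo) < y0:
            break
        lo -= 1.0
    for _ in range(20):
        if logpost(hi) < y0:
            break
        hi += 1.0
    for _ in range(50):
        x1 = rng.uniform(lo, hi)
        if logpost(x1) >= y0:
            return math.exp(x1)
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return sigma2


def sample_posterior(
    inputs: ModelInputs,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Draw from the posterior of the full hierarchical model.

    Runs ``mcmc.n_chains`` independent Gibbs chains (seeded from
    ``mcmc.seed`` via named substreams, so identical inputs and seed give
    identical draws), discards burn-in, thins, and flags convergence via
    rank-normalized split-R-hat on the intercept, effective coefficients
    and residual sd (warning threshold 1.1).
    """
    priors = priors or (inputs.spec.priors if inputs.spec else PriorSpec())
    mcmc = mcmc or McmcConfig()
    for f, labels in inputs.group_labels.items():
        if len(labels) < 2:
            raise ValueError(f"grouping factor {f!r} needs >= 2 levels")
    mu0 = inputs.X @ np.zeros(inputs.n_terms)
    if not np.all(np.isfinite(mu0)):
        raise ValueError("non-finite design matrix")

    C, S, p = mcmc.n_chains, mcmc.n_draws, inputs.n_terms
    levels = list(inputs.group_idx)
    store = {
        "alpha": np.empty((C, S)),
        "b": np.empty((C, S, p)),
        "gamma": np.empty((C, S, p)),
        "sigma": np.empty((C, S)),
        "tau": {f: np.empty((C, S)) for f in levels},
        "u": {f: np.empty((C, S, len(inputs.group_labels[f]))) for f in levels},
    }
    seeds = np.random.SeedSequence(mcmc.seed).spawn(C)
    for c in range(C):
        _run_chain(inputs, priors, mcmc, np.random.default_rng(seeds[c]), store, c)

    samples = PosteriorSamples(
        terms=list(inputs.terms), selectable=inputs.selectable.copy(),
        alpha=store["alpha"], b=store["b"], gamma=store["gamma"],
        sigma=store["sigma"], tau=store["tau"], u=store["u"],
        group_labels={f: list(v) for f, v in inputs.group_labels.items()},
        seed=mcmc.seed,
    )
    if check_convergence and C >= 2 and S >= 10:
        import arviz as az

        monitored = [samples.alpha, samples.sigma] + [
            samples.beta[:, :, j] for j in range(p) if not inputs.selectable[j]
        ]
        rhats = [float(az.rhat(az.convert_to_dataset(m))["x"]) for m in monitored]
        samples.max_rhat = float(np.nanmax(rhats))
        samples.converged = bool(samples.max_rhat < 1.1)
    return samples


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_rate(
    samples: PosteriorSamples,
    covariates: Mapping[str, float] | None = None,
    include: set[str] | None = None,
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Posterior predictive linear predictor (% per year) at covariate values.

    Unspecified covariates sit at 0 (the mean, since covariates are
    z-transformed).  Interaction terms are formed from their parents'
    values.  With ``groups`` given, the named random intercepts are
    added; otherwise prediction is at the population level (random
    effects at 0).  Returns the per-draw values with median and nested
    50/80/95% intervals.
    """
    covariates = dict(covariates or {})
    x = np.zeros(len(samples.terms))
    for j, t in enumerate(samples.terms):
        if ":" in t:
            a, b_ = t.split(":")
            x[j] = covariates.get(a, 0.0) * covariates.get(b_, 0.0)
        else:
            x[j] = covariates.get(t, 0.0)
    unknown = set(covariates) - {t for t in samples.terms if ":" not in t}
    if unknown:
        raise ValueError(f"unknown covariate names: {sorted(unknown)}")

    beta = samples.flat(samples.beta)
    if include is not None:
        mask = np.array([t in include for t in samples.terms], dtype=float)
        beta = beta * mask
    draws = samples.alpha.ravel() + beta @ x
    if groups:
        for level, label in groups.items():
            if level not in samples.u:
                raise ValueError(f"unknown grouping level: {level}")
            labels = samples.group_labels[level]
            if label not in labels:
                raise ValueError(f"unknown {level} label: {label!r}")
            draws = draws + samples.flat(samples.u[level])[:, labels.index(label)]

    qs = {
        50: tuple(np.quantile(draws, [0.25, 0.75])),
        80: tuple(np.quantile(draws, [0.10, 0.90])),
        95: tuple(np.quantile(draws, [0.025, 0.975])),
    }
    return {"draws": draws, "median": float(np.median(draws)), "intervals": qs}
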