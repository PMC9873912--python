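"""Convergence, residual and fit diagnostics for a fitted model.

Covers rank-normalized split-R-hat and effective sample size (via
ArviZ), Moran's I with inverse great-circle-distance weights and a
permutation test (spatial autocorrelation of residuals), Pagel's lambda
on per-species residuals (phylogenetic autocorrelation), posterior
predictive checks, and conditional / marginal R-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "rhat",
    "ess",
    "morans_i",
    "pagels_lambda",
    "taxonomy_vcv",
    "vcv_from_tree",
    "species_residuals",
    "posterior_predictive_check",
    "conditional_r2",
    "DiagnosticsReport",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DiagnosticsReport:
    rhat: dict[str, float]
    ess: dict[str, float]
    morans: tuple[float, float, float] | None  # (I, E[I], p)
    pagel: tuple[float, float] | None          # (lambda, p)
    ppc: pd.DataFrame | None
    r2_conditional: float
    r2_marginal: float

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess": self.ess,
            "morans_i": None if self.morans is None else {
                "I": self.morans[0], "expected": self.morans[1], "p": self.morans[2]},
            "pagels_lambda": None if self.pagel is None else {
                "lambda": self.pagel[0], "p": self.pagel[1]},
            "r2_conditional": self.r2_conditional,
            "r2_marginal": self.r2_marginal,
        }


def rhat(chains) -> float:
    """Rank-normalized split-R-hat across chains of one parameter.

    ``chains`` is (n_chains, n_draws); values near 1 indicate the chains
    agree in location and spread.
    """
    import arviz as az

    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    if arr.shape[1] < 10:
        raise ValueError("need >= 10 draws per chain")
    return float(az.rhat(az.convert_to_dataset(arr))["x"])


def ess(chains) -> float:
    """Bulk effective sample size across chains of one parameter."""
    import arviz as az

    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("need a (chains, draws) array")
    return float(az.ess(az.convert_to_dataset(arr))["x"])


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi[:, None]) * np.cos(phi[None, :]) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def morans_i(
    residuals,
    latitude,
    longitude,
    n_permutations: int = 999,
    seed: int = 0,
    jitter: bool = False,
) -> tuple[float, float, float]:
    """Moran's I of residuals under inverse great-circle-distance weights.

    Weights are ``1/d_ij`` (zero diagonal), row-standardized.  Returns
    ``(I, E[I], p)`` where ``E[I] = -1/(n-1)`` and ``p`` is the
    two-sided permutation p-value from shuffling residuals over
    locations.  Duplicate coordinates are rejected unless ``jitter``
    adds a small deterministic offset.
    """
    z = np.asarray(residuals, dtype=float)
    lat = np.asarray(latitude, dtype=float).copy()
    lon = np.asarray(longitude, dtype=float).copy()
    n = z.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.std(z) == 0:
        raise ValueError("Moran's I undefined for constant residuals")
    d = _haversine_matrix(lat, lon)
    off = d[~np.eye(n, dtype=bool)]
    if np.any(off == 0):
        if not jitter:
            raise ValueError("duplicate coordinates; pass jitter=True")
        rng_j = np.random.default_rng(12345)
        lat += rng_j.normal(0, 1e-3, n)
        lon += rng_j.normal(0, 1e-3, n)
        d = _haversine_matrix(lat, lon)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)

    zc = z - z.mean()
    denom = float(zc @ zc)

    def stat(v):
        return float(v @ (w @ v)) / denom

    i_obs = stat(zc)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(zc)
        if abs(stat(perm) - expected) >= abs(i_obs - expected) - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return i_obs, expected, p


def taxonomy_vcv(species_to_genus: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Two-level taxonomy covariance with unit branch lengths.

    Stand-in phylogeny when no Newick tree is supplied: root -> genus ->
    species, each branch length 1, so tips share covariance 1 within a
    genus, 0 across genera, with tip variance 2.
    """
    species = sorted(species_to_genus)
    genera = [species_to_genus[s] for s in species]
    n = len(species)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                V[i, j] = 2.0
            elif genera[i] == genera[j]:
                V[i, j] = 1.0
    return species, V


def vcv_from_tree(tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance (shared root-path lengths) from a tree.

    ``tree`` is a :class:`dendropy.Tree` with branch lengths; the
    covariance of tips i, j is the length of their shared path from the
    root.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon] = leaf.distance_from_root()
    labels = [t.label for t in taxa]
    n = len(taxa)
    V = np.zeros((n, n))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i == j:
                V[i, j] = depth[ti]
            else:
                V[i, j] = 0.5 * (depth[ti] + depth[tj] - pdm.patristic_distance(ti, tj))
    return labels, V


def species_residuals(residuals, species) -> tuple[list[str], np.ndarray]:
    """Mean residual per species (tips of the phylogeny)."""
    df = pd.DataFrame({"species": species, "resid": np.asarray(residuals, float)})
    agg = df.groupby("species")["resid"].mean().sort_index()
    return list(agg.index), agg.to_numpy()


def _lambda_loglik(lam: float, y: np.ndarray, V: np.ndarray) -> float:
    n = y.size
    Vl = lam * V + (1 - lam) * np.diag(np.diag(V))
    try:
        L = np.linalg.cholesky(Vl)
    except np.linalg.LinAlgError:
        return -np.inf
    ones = np.ones(n)
    Vi_y = np.linalg.solve(Vl, y)
    Vi_1 = np.linalg.solve(Vl, ones)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    r = y - mu
    Vi_r = np.linalg.solve(Vl, r)
    sigma2 = max(float(r @ Vi_r) / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def pagels_lambda(
    residuals,
    species: list[str] | None = None,
    tree=None,
    species_to_genus: dict[str, str] | None = None,
    vcv: tuple[list[str], np.ndarray] | None = None,
) -> tuple[float, float]:
    """Maximum-likelihood Pagel's lambda of per-species residuals.

    Lambda scales the off-diagonal Brownian covariance of the tree
    (``vcv``, a Newick ``tree``, or the genus/species taxonomy stand-in)
    between 0 (no phylogenetic signal) and 1 (full Brownian signal).
    Returns ``(lambda_hat, p)`` where ``p`` is from a likelihood-ratio
    test against lambda = 0 (chi-squared, 1 df).  A star phylogeny has no
    off-diagonal structure; lambda is then 0 by convention with p = 1.
    """
    if vcv is not None:
        labels, V = vcv
    elif tree is not None:
        labels, V = vcv_from_tree(tree)
    elif species_to_genus is not None:
        labels, V = taxonomy_vcv(species_to_genus)
    else:
        raise ValueError("supply vcv, tree, or species_to_genus")

    y = np.asarray(residuals, dtype=float)
    if species is not None:
        missing = sorted(set(species) - set(labels))
        if missing:
            raise ValueError(f"species missing from tree: {missing}")
        order = [labels.index(s) for s in species]
        V = V[np.ix_(order, order)]
    elif y.size != V.shape[0]:
        raise ValueError("residual length must match tree tips (or pass species)")

    off = V[~np.eye(V.shape[0], dtype=bool)]
    if np.allclose(off, 0.0):
        return 0.0, 1.0

    res = optimize.minimize_scalar(
        lambda lam: -_lambda_loglik(lam, y, V),
        bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6},
    )
    lam_hat = float(res.x)
    ll1 = _lambda_loglik(lam_hat, y, V)
    ll0 = _lambda_loglik(0.0, y, V)
    lr = max(2.0 * (ll1 - ll0), 0.0)
    p = float(chi2.sf(lr, df=1))
    return lam_hat, p


def _mu_matrix(samples, inputs) -> np.ndarray:
    """Per-draw linear predictor (draws x records), random effects included."""
    beta = samples.flat(samples.beta)             # (D, p)
    mu = samples.alpha.ravel()[:, None] + beta @ inputs.X.T
    for level, idx in inputs.group_idx.items():
        mu += samples.flat(samples.u[level])[:, idx]
    return mu


def posterior_predictive_check(
    samples,
    inputs,
    n_draws: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs replicate-response summaries.

    For a subsample of posterior draws, replicate responses are
    simulated from the fitted likelihood (censored records simulated
    then categorized by the non-overlapping partition at +-5).  Reports
    the 5/25/50/75/95% quantiles of quantitative records and the
    qualitative category proportions, with the central 95% interval of
    each statistic across replicates and a coverage flag.
    """
    from carnitrend.synthetic import categorize_trend

    if inputs.n == 0:
        raise ValueError("no records")
    rng = np.random.default_rng(seed)
    total = samples.n_draws_total
    take = rng.choice(total, size=min(n_draws, total), replace=False)
    mu = _mu_matrix(samples, inputs)[take]
    sd = (samples.sigma.ravel()[take][:, None]
          / np.sqrt(inputs.w)[None, :])
    y_rep = rng.normal(mu, sd)

    quant = ~inputs.is_censored
    qs = [5, 25, 50, 75, 95]
    rows = []
    obs_q = np.percentile(inputs.y[quant], qs)
    rep_q = np.percentile(y_rep[:, quant], qs, axis=1)   # (5, D)
    for k, q in enumerate(qs):
        lo, hi = np.percentile(rep_q[k], [2.5, 97.5])
        rows.append({
            "statistic": f"q{q}", "observed": obs_q[k],
            "replicate_median": float(np.median(rep_q[k])),
            "replicate_lo95": lo, "replicate_hi95": hi,
            "within_95": bool(lo <= obs_q[k] <= hi),
        })
    if inputs.is_censored.any():
        cens_cols = np.flatnonzero(inputs.is_censored)
        obs_cat = pd.Series([
            "Decrease" if inputs.upper[i] <= 0 else
            ("Increase" if inputs.lower[i] >= 0 else "Stable")
            for i in cens_cols
        ])
        rep_cens = y_rep[:, cens_cols]
        for cat in ("Decrease", "Stable", "Increase"):
            obs_p = float((obs_cat == cat).mean())
            rep_p = np.array([
                np.mean([categorize_trend(v) == cat for v in row])
                for row in rep_cens
            ])
            lo, hi = np.percentile(rep_p, [2.5, 97.5])
            rows.append({
                "statistic": f"prop_{cat}", "observed": obs_p,
                "replicate_median": float(np.median(rep_p)),
                "replicate_lo95": lo, "replicate_hi95": hi,
                "within_95": bool(lo - 1e-12 <= obs_p <= hi + 1e-12),
            })
    return pd.DataFrame(rows)


def conditional_r2(samples, inputs) -> tuple[float, float]:
    """Conditional and marginal R-squared of the mixed model.

    Per draw: marginal R2 = var(fixed) / (var(fixed) + sum tau_f^2 +
    sigma^2); conditional adds the random-intercept variances to the
    numerator.  Returns the medians across draws.
    """
    beta = samples.flat(samples.beta)
    fixed = beta @ inputs.X.T                       # (D, n)
    var_f = fixed.var(axis=1)
    var_r = sum(samples.flat(t) ** 2 for t in samples.tau.values()).ravel()
    sig2 = samples.sigma.ravel() ** 2
    total = var_f + var_r + sig2
    marg = var_f / total
    cond = (var_f + var_r) / total
    return float(np.median(cond)), float(np.median(marg))
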