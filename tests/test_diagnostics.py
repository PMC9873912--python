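"""Convergence, spatial / phylogenetic autocorrelation and fit diagnostics."""

import math

import numpy as np
import pytest

from carnitrend import diagnostics
from carnitrend.diagnostics import (
    conditional_r2,
    morans_i,
    pagels_lambda,
    posterior_predictive_check,
    rhat,
    taxonomy_vcv,
)
from carnitrend.model import PosteriorSamples


class TestRhat:
    def test_identical_stationary_chains(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(5000)
        assert rhat(np.stack([chain, chain + 1e-12])) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_diverge(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(-10, 1, 500), rng.normal(10, 1, 500)])
        assert rhat(chains) > 1.5

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(2)
        assert rhat(rng.standard_normal((3, 10_000))) < 1.01

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestMoransI:
    def _coords(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(-50, 60, n), rng.uniform(-170, 170, n)

    def test_expected_value_analytic(self):
        lat, lon = self._coords(11, seed=3)
        rng = np.random.default_rng(4)
        i_obs, expected, p = morans_i(rng.standard_normal(11), lat, lon,
                                      n_permutations=199, seed=5)
        assert expected == pytest.approx(-1 / 10)
        assert p > 0.05  # iid residuals: inside the permutation null band

    def test_mean_of_permutation_null_matches_expectation(self):
        """E[I] = -1/(n-1) for any row-standardized weights (permutation mean)."""
        n = 9
        lat, lon = self._coords(n, seed=6)
        rng = np.random.default_rng(7)
        z = rng.standard_normal(n)
        stats = []
        d = diagnostics._haversine_matrix(lat, lon)
        w = 1.0 / d
        np.fill_diagonal(w, 0)
        w /= w.sum(axis=1, keepdims=True)
        zc = z - z.mean()
        # brute force over many permutations
        for _ in range(4000):
            v = rng.permutation(zc)
            stats.append(float(v @ w @ v) / float(zc @ zc))
        assert np.mean(stats) == pytest.approx(-1 / (n - 1), abs=0.01)

    def test_smooth_latitude_signal_detected(self):
        lat, lon = self._coords(60, seed=8)
        resid = lat / 30.0  # deterministic smooth spatial field
        i_obs, _, p = morans_i(resid, lat, lon, n_permutations=999, seed=9)
        assert i_obs > 0.1
        assert p < 0.01

    def test_deterministic_p_under_seed(self):
        lat, lon = self._coords(25, seed=10)
        rng = np.random.default_rng(11)
        z = rng.standard_normal(25)
        p1 = morans_i(z, lat, lon, n_permutations=199, seed=12)[2]
        p2 = morans_i(z, lat, lon, n_permutations=199, seed=12)[2]
        assert p1 == p2

    def test_constant_residuals_rejected(self):
        lat, lon = self._coords(10, seed=13)
        with pytest.raises(ValueError):
            morans_i(np.ones(10), lat, lon)

    def test_duplicate_coordinates_need_jitter(self):
        lat = np.array([0.0, 0.0, 10, 20, 30, 40.0])
        lon = np.array([5.0, 5.0, 10, 20, 30, 40.0])
        z = np.arange(6.0)
        with pytest.raises(ValueError, match="jitter"):
            morans_i(z, lat, lon)
        morans_i(z, lat, lon, n_permutations=49, seed=1, jitter=True)


def _simulate_brownian(V, seed, sigma=1.0):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    return L @ rng.standard_normal(len(V)) * sigma


@pytest.fixture(scope="module")
def vcv():
    s2g = {f"sp{i:02d}": f"gen{i % 12:02d}" for i in range(48)}
    return taxonomy_vcv(s2g)


class TestPagelsLambda:

    def test_iid_tips_give_small_lambda(self, vcv):
        labels, V = vcv
        hits = 0
        for k in range(30):
            y = np.random.default_rng(100 + k).standard_normal(len(labels))
            lam, p = pagels_lambda(y, vcv=(labels, V))
            if p > 0.05:
                hits += 1
        assert hits >= 24  # LR test non-significant in the large majority

    def test_brownian_tips_give_large_lambda(self, vcv):
        labels, V = vcv
        lams = [pagels_lambda(_simulate_brownian(V, 200 + k), vcv=vcv)[0]
                for k in range(20)]
        assert np.median(lams) > 0.8

    def test_star_phylogeny_lambda_zero(self):
        labels = [f"s{i}" for i in range(10)]
        V = np.eye(10) * 1.7
        lam, p = pagels_lambda(np.random.default_rng(5).standard_normal(10),
                               vcv=(labels, V))
        assert lam == 0.0 and p == 1.0

    def test_branch_length_scale_invariance(self, vcv):
        labels, V = vcv
        y = _simulate_brownian(V, 303)
        lam1, _ = pagels_lambda(y, vcv=(labels, V))
        lam2, _ = pagels_lambda(y, vcv=(labels, 7.3 * V))
        assert lam1 == pytest.approx(lam2, abs=1e-4)

    def test_missing_species_listed(self, vcv):
        labels, V = vcv
        with pytest.raises(ValueError, match="missing"):
            pagels_lambda(np.zeros(2), species=["sp00", "not_in_tree"],
                          vcv=(labels, V))

    def test_newick_tree_vcv_matches_taxonomy(self, tmp_path):
        import dendropy

        newick = "((a:1,b:1):1,(c:1,d:1):1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels, V = diagnostics.vcv_from_tree(tree)
        assert labels == ["a", "b", "c", "d"]
        np.testing.assert_allclose(np.diag(V), 2.0)
        assert V[labels.index("a"), labels.index("b")] == pytest.approx(1.0)
        assert V[labels.index("a"), labels.index("c")] == pytest.approx(0.0)


class TestPosteriorPredictive:
    def test_self_consistency(self, small_fit, small_inputs):
        """Data simulated from the model itself passes its own check."""
        ppc = posterior_predictive_check(small_fit, small_inputs, seed=0)
        row = ppc[ppc["statistic"] == "q50"].iloc[0]
        assert row["within_95"]

    def test_shifted_response_flagged(self, small_fit, small_inputs):
        import dataclasses

        shifted = dataclasses.replace(small_inputs, y=small_inputs.y + 50.0)
        ppc = posterior_predictive_check(small_fit, shifted, seed=0)
        row = ppc[ppc["statistic"] == "q50"].iloc[0]
        assert not row["within_95"]

    def test_zero_records_rejected(self, small_fit, small_inputs):
        import dataclasses

        empty = dataclasses.replace(
            small_inputs, y=np.empty(0), is_censored=np.empty(0, bool))
        with pytest.raises(ValueError):
            posterior_predictive_check(small_fit, empty)


def _fake_samples(beta_draws, tau_value, sigma_value, terms):
    """Hand-built PosteriorSamples with known variance components."""
    D = beta_draws.shape[0]
    p = beta_draws.shape[1]
    return PosteriorSamples(
        terms=terms, selectable=np.zeros(p, bool),
        alpha=np.zeros((1, D)), b=beta_draws[None, :, :],
        gamma=np.ones((1, D, p)), sigma=np.full((1, D), sigma_value),
        tau={"genus": np.full((1, D), tau_value)},
        u={"genus": np.zeros((1, D, 2))},
        group_labels={"genus": ["g0", "g1"]}, seed=0,
    )


class TestConditionalR2:
    def _inputs(self, X):
        import dataclasses

        from carnitrend.model import ModelInputs, ModelSpec

        n = X.shape[0]
        return ModelInputs(
            y=np.zeros(n), is_censored=np.zeros(n, bool),
            lower=np.full(n, np.nan), upper=np.full(n, np.nan),
            X=X, terms=[f"t{j}" for j in range(X.shape[1])],
            selectable=np.zeros(X.shape[1], bool), w=np.ones(n),
            se_pct=np.zeros(n), group_idx={"genus": np.zeros(n, np.int64)},
            group_labels={"genus": ["g0", "g1"]}, me_columns=[],
            standardization={}, spec=None, population_ids=[str(i) for i in range(n)],
        )

    def test_noiseless_fixed_effects_give_unity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 1))
        samples = _fake_samples(np.full((50, 1), 2.0), 0.0, 1e-9, ["t0"])
        cond, marg = conditional_r2(samples, self._inputs(X))
        assert cond == pytest.approx(1.0, abs=1e-6)
        assert marg == pytest.approx(1.0, abs=1e-6)

    def test_null_model_gives_zero(self):
        X = np.random.default_rng(1).standard_normal((200, 1))
        samples = _fake_samples(np.zeros((50, 1)), 0.0, 3.0, ["t0"])
        cond, marg = conditional_r2(samples, self._inputs(X))
        assert cond == 0.0 and marg == 0.0

    def test_known_variance_partition(self):
        """Fixed 0.4 / random 0.3 / residual 0.3 => marginal 0.4, conditional 0.7."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4000, 1))
        samples = _fake_samples(
            np.full((50, 1), math.sqrt(0.4)), math.sqrt(0.3), math.sqrt(0.3), ["t0"])
        cond, marg = conditional_r2(samples, self._inputs(X))
        assert marg == pytest.approx(0.4, abs=0.05)
        assert cond == pytest.approx(0.7, abs=0.05)

    def test_conditional_at_least_marginal(self, small_fit, small_inputs):
        cond, marg = conditional_r2(small_fit, small_inputs)
        assert 0.0 <= marg <= cond <= 1.0
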