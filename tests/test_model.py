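"""Censored likelihood, weighting, design construction and the sampler."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from carnitrend import model, synthetic, terms
from carnitrend.model import (
    McmcConfig,
    ModelSpec,
    PriorSpec,
    QualityMeta,
    build_design,
    censored_loglik,
    inclusion_probabilities,
    predict_rate,
    sample_posterior,
    weight_precision,
)


def _quadrature_logmass(mu: float, sigma: float, lo: float, up: float) -> float:
    """Independent oracle: log integral of the normal pdf over (lo, up),
    via adaptive quadrature of exp(logpdf - M) with M at the interval peak."""
    import warnings

    def logpdf(x):
        return stats.norm.logpdf(x, mu, sigma)

    peak = min(max(mu, lo), up)
    M = max(logpdf(lo), logpdf(up), logpdf(peak))
    pts = [peak] if lo < peak < up else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val, _ = integrate.quad(lambda x: math.exp(logpdf(x) - M), lo, up,
                                epsabs=1e-300, epsrel=1e-12, limit=500, points=pts)
    return M + math.log(val)


class TestCensoredLoglik:
    def test_standard_normal_band(self):
        # P(0 < X < 50) with mu=0, sigma=50 is Phi(1) - Phi(0)
        expected = math.log(stats.norm.cdf(1) - stats.norm.cdf(0))
        assert censored_loglik(0.0, 50.0, (0.0, 50.0)) == pytest.approx(expected, abs=1e-10)
        assert censored_loglik(0.0, 50.0, (0.0, 50.0)) == pytest.approx(-1.0748, abs=1e-3)

    def test_full_support_is_certain(self):
        assert censored_loglik(0.0, 1.0, (-1e9, 1e9)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_mu_for_symmetric_interval(self):
        for c in (0.3, 2.0, 17.5):
            assert censored_loglik(c, 3.0, (-5, 5)) == pytest.approx(
                censored_loglik(-c, 3.0, (-5, 5)), rel=1e-12)

    def test_agrees_with_quadrature_including_tails(self):
        """Adaptive quadrature of the normal density (peak-scaled so extreme
        tails stay representable) reproduces the log-space formula."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            mu = rng.uniform(-60, 60)
            sigma = 10 ** rng.uniform(-1, 1.5)
            lo = rng.uniform(-60, 40)
            up = lo + 10 ** rng.uniform(-1, 1.7)
            assert censored_loglik(mu, sigma, (lo, up)) == pytest.approx(
                _quadrature_logmass(mu, sigma, lo, up), abs=1e-8)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            censored_loglik(0.0, 1.0, (5.0, -5.0))


class TestWeightPrecision:
    @pytest.mark.parametrize("quality, expected", [
        (QualityMeta(10, 10, 3), 1.0),
        (QualityMeta(2.5, 10, 3), 0.5),
        (QualityMeta(10, 10, 1), 1 / 3),
    ])
    def test_reference_values(self, quality, expected):
        assert weight_precision(quality) == pytest.approx(expected)

    def test_monotone_in_each_component(self):
        base = weight_precision(QualityMeta(5, 5, 2))
        assert weight_precision(QualityMeta(8, 5, 2)) >= base
        assert weight_precision(QualityMeta(5, 8, 2)) >= base
        assert weight_precision(QualityMeta(5, 5, 3)) >= base

    def test_invalid_quality_rejected(self):
        with pytest.raises(ValueError):
            QualityMeta(0, 5, 2)
        with pytest.raises(ValueError):
            QualityMeta(5, 5, 4)


class TestBuildDesign:
    def test_full_spec_has_23_columns(self, small_dataset, small_inputs):
        assert small_inputs.X.shape == (len(small_dataset["trend"]), 23)
        assert small_inputs.n_terms == 23
        assert small_inputs.selectable.sum() == 16  # 9 optional + 7 interactions

    def test_censor_flags(self, small_dataset, small_inputs):
        trend = small_dataset["trend"]
        stable = trend.index[(trend["category"] == "Stable")]
        assert len(stable) > 0
        for i in stable:
            assert (small_inputs.lower[i], small_inputs.upper[i]) == (-5.0, 5.0)

    def test_empty_interactions_gives_main_effects_only(self, small_dataset):
        spec = ModelSpec(interaction_terms=())
        inputs = build_design(small_dataset["trend"], small_dataset["cov_imputed"], spec)
        assert inputs.n_terms == 16

    def test_unmatched_population_rejected(self, small_dataset):
        cov = small_dataset["cov_imputed"].iloc[:-5]
        with pytest.raises(ValueError, match="no covariate row"):
            build_design(small_dataset["trend"], cov)

    def test_unknown_covariate_rejected(self, small_dataset):
        spec = ModelSpec(core_terms=("body_mass", "not_a_covariate"),
                         optional_terms=(), interaction_terms=())
        with pytest.raises(ValueError, match="unknown covariate"):
            build_design(small_dataset["trend"], small_dataset["cov_imputed"], spec)

    def test_measurement_error_cells_registered(self, small_dataset, small_inputs):
        n_sd_cells = int(sum(
            small_dataset["cov_imputed"][c].notna().sum()
            for c in small_dataset["cov_imputed"].columns if c.endswith("__sd")))
        assert sum(mc.rows.size for mc in small_inputs.me_columns) == n_sd_cells


class TestSampler:
    def test_identical_seed_identical_draws(self, small_inputs):
        mcmc = McmcConfig(n_chains=2, n_iterations=300, n_burnin=100, thin=2, seed=9)
        s1 = sample_posterior(small_inputs, mcmc=mcmc, check_convergence=False)
        s2 = sample_posterior(small_inputs, mcmc=mcmc, check_convergence=False)
        np.testing.assert_array_equal(s1.alpha, s2.alpha)
        np.testing.assert_array_equal(s1.b, s2.b)
        np.testing.assert_array_equal(s1.gamma, s2.gamma)

    def test_matches_wls_oracle_without_hierarchy(self):
        """With variance components at 0 and no selection, posterior medians of
        the intercept and slopes agree with closed-form weighted least squares."""
        rng = np.random.default_rng(21)
        n = 400
        cfg = synthetic.SyntheticConfig(
            n_populations=n, frac_qualitative=0.0, missing_rate=0.0,
            true_betas={"body_mass": 1.0, "governance": -0.8},
            sd_random={lvl: 0.0 for lvl in synthetic.RANDOM_LEVELS}, seed=22)
        trend, cov, _ = synthetic.generate_dataset(cfg)
        spec = ModelSpec(core_terms=("body_mass", "governance"),
                         optional_terms=(), interaction_terms=())
        inputs = build_design(trend, cov, spec)
        mcmc = McmcConfig(n_chains=2, n_iterations=1500, n_burnin=500, thin=2, seed=23)
        samples = sample_posterior(inputs, mcmc=mcmc, check_convergence=False)

        X = np.column_stack([np.ones(n), inputs.X])
        W = np.diag(inputs.w)
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ inputs.y)
        post = np.column_stack([samples.alpha.ravel(),
                                samples.flat(samples.beta)])
        for j in range(3):
            med = np.median(post[:, j])
            sd = post[:, j].std()
            assert abs(med - coef[j]) < 2 * sd

    def test_requires_two_levels_per_group(self, small_dataset):
        trend = small_dataset["trend"].copy()
        trend["subregion"] = "only_one"
        inputs = build_design(trend, small_dataset["cov_imputed"])
        with pytest.raises(ValueError, match="levels"):
            sample_posterior(inputs, mcmc=McmcConfig(n_chains=1, n_iterations=20,
                                                     n_burnin=10, seed=1))

    def test_pinned_term_has_inclusion_one(self, small_dataset):
        spec = ModelSpec(pinned_terms=("change_human_development",))
        inputs = build_design(small_dataset["trend"], small_dataset["cov_imputed"], spec)
        mcmc = McmcConfig(n_chains=1, n_iterations=300, n_burnin=100, thin=2, seed=31)
        samples = sample_posterior(inputs, mcmc=mcmc, check_convergence=False)
        incl = inclusion_probabilities(samples)
        assert incl["change_human_development"] == 1.0

    def test_permutation_of_records_equivalent(self, small_dataset):
        """Record order must not change posterior location beyond MC error."""
        trend = small_dataset["trend"]
        cov = small_dataset["cov_imputed"]
        mcmc = McmcConfig(n_chains=1, n_iterations=1200, n_burnin=400, thin=2, seed=41)
        s1 = sample_posterior(build_design(trend, cov), mcmc=mcmc,
                              check_convergence=False)
        perm = np.random.default_rng(42).permutation(len(trend))
        s2 = sample_posterior(build_design(trend.iloc[perm].reset_index(drop=True),
                                           cov), mcmc=mcmc, check_convergence=False)
        a1, a2 = s1.alpha.ravel(), s2.alpha.ravel()
        pooled_sd = math.hypot(a1.std(), a2.std())
        assert abs(a1.mean() - a2.mean()) < 3 * pooled_sd


class TestPersistence:
    def test_long_csv_round_trip(self, small_fit, tmp_path):
        from carnitrend.model import PosteriorSamples

        small_fit.save(tmp_path / "post")
        back = PosteriorSamples.load(tmp_path / "post")
        np.testing.assert_array_equal(back.alpha, small_fit.alpha)
        np.testing.assert_array_equal(back.b, small_fit.b)
        np.testing.assert_array_equal(back.gamma, small_fit.gamma)
        np.testing.assert_array_equal(back.u["genus"], small_fit.u["genus"])
        assert back.terms == small_fit.terms
        np.testing.assert_array_equal(back.selectable, small_fit.selectable)


class TestInclusionAndPrediction:
    def test_inclusion_map_covers_selectable_terms(self, small_fit):
        incl = inclusion_probabilities(small_fit)
        assert len(incl) == 16
        assert all(0.0 <= v <= 1.0 for v in incl.values())

    def test_core_term_not_under_selection(self, small_fit):
        with pytest.raises(ValueError, match="not under selection"):
            inclusion_probabilities(small_fit, "body_mass")

    def test_prediction_at_zero_is_intercept(self, small_fit):
        pred = predict_rate(small_fit)
        np.testing.assert_allclose(pred["draws"], small_fit.alpha.ravel())

    def test_prediction_shifts_linearly(self, small_fit):
        j = small_fit.terms.index("body_mass")
        beta_med = float(np.median(small_fit.flat(small_fit.beta)[:, j]))
        base = predict_rate(small_fit)["median"]
        shifted = predict_rate(small_fit, {"body_mass": 1.0})["median"]
        spread = small_fit.flat(small_fit.beta)[:, j].std() + 1e-9
        assert abs((shifted - base) - beta_med) < 3 * spread

    def test_intervals_nest(self, small_fit):
        pred = predict_rate(small_fit, {"governance": 2.0})
        (l50, u50), (l80, u80), (l95, u95) = (pred["intervals"][k] for k in (50, 80, 95))
        assert l95 <= l80 <= l50 <= u50 <= u80 <= u95

    def test_unknown_group_label_rejected(self, small_fit):
        with pytest.raises(ValueError, match="unknown"):
            predict_rate(small_fit, groups={"genus": "no_such_genus"})

    def test_group_prediction_adds_intercept(self, small_fit):
        label = small_fit.group_labels["genus"][0]
        with_u = predict_rate(small_fit, groups={"genus": label})["draws"]
        u = small_fit.flat(small_fit.u["genus"])[:, 0]
        np.testing.assert_allclose(with_u, small_fit.alpha.ravel() + u)


class TestCensoredIntegration:
    def test_record_and_frame_paths_agree(self, small_dataset, tmp_path):
        """Fitting from validated TrendRecord objects equals fitting from the
        raw table once all qualitative records are filtered out."""
        from carnitrend.pipeline import load_trend_table

        trend = small_dataset["trend"]
        quant = trend[trend["response_kind"] == "quantitative"].reset_index(drop=True)
        cov = small_dataset["cov_imputed"]
        path = tmp_path / "quant.csv"
        quant.to_csv(path, index=False, float_format="%.17g")
        records = load_trend_table(path)
        mcmc = McmcConfig(n_chains=1, n_iterations=400, n_burnin=200, thin=2, seed=51)
        s1 = sample_posterior(build_design(quant, cov), mcmc=mcmc,
                              check_convergence=False)
        s2 = sample_posterior(build_design(records, cov), mcmc=mcmc,
                              check_convergence=False)
        np.testing.assert_array_equal(s1.alpha, s2.alpha)
        np.testing.assert_array_equal(s1.b, s2.b)
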