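"""Counterfactual scenarios and human-development pathway projections."""

import numpy as np
import pytest

from carnitrend import scenarios
from carnitrend.scenarios import (
    DEFAULT_PATHWAYS,
    PathwayScenario,
    ScenarioSpec,
    counterfactual_diff,
    hd_pathway,
    project_abundance,
    turning_point,
)

MODERATE = PathwayScenario("Moderate", 1.5)


class TestPathway:
    def test_moderate_endpoints(self):
        years, dhd, hdi = hd_pathway(MODERATE)
        assert dhd[list(years).index(1960)] == pytest.approx(2.1)
        assert dhd[list(years).index(2020)] == pytest.approx(0.9)

    def test_first_compounding_step(self):
        years, dhd, hdi = hd_pathway(MODERATE)
        assert hdi[list(years).index(1961)] == pytest.approx(0.2 * 1.021)

    def test_mean_change_equals_pace(self):
        for pw in DEFAULT_PATHWAYS:
            _, dhd, _ = hd_pathway(pw)
            assert dhd.mean() == pytest.approx(pw.pace, abs=1e-12)

    def test_zero_deceleration_is_geometric(self):
        pw = PathwayScenario("flat", 1.0, deceleration=0.0)
        years, dhd, hdi = hd_pathway(pw)
        np.testing.assert_allclose(dhd, 1.0)
        np.testing.assert_allclose(hdi, 0.2 * 1.01 ** np.arange(years.size))

    def test_index_cannot_exceed_one(self):
        pw = PathwayScenario("too_fast", 5.0, deceleration=0.0, hd0=0.9)
        with pytest.raises(ValueError, match="above 1"):
            hd_pathway(pw)

    def test_change_series_is_linear(self):
        _, dhd, _ = hd_pathway(MODERATE)
        np.testing.assert_allclose(np.diff(dhd), MODERATE.deceleration, atol=1e-12)


class TestProjection:
    STD = (1.2, 0.5)  # covariate standardization: mean 1.2 %/yr, sd 0.5

    def test_null_effect_is_flat(self):
        res = project_abundance(np.zeros(100), self.STD, MODERATE)
        np.testing.assert_allclose(res.median, 100.0)
        np.testing.assert_allclose(res.lo95, 100.0)

    def test_u_shape_with_negative_effect(self):
        """beta < 0 and a pathway crossing g=0: decline then recovery, with
        the minimum at the year the pathway crosses the covariate mean."""
        res = project_abundance(np.full(50, -0.44), self.STD, MODERATE)
        d = np.diff(res.median)
        k_min = int(np.argmin(res.median))
        crossing = 2005  # 1990 + (1.5 - 1.2) / 0.02
        assert res.years[k_min] == crossing
        assert np.all(d[:list(res.years).index(crossing)] < 0)
        assert np.all(d[list(res.years).index(crossing) + 1:] > 0)

    def test_baseline_linearity(self):
        res1 = project_abundance(np.full(20, -0.3), self.STD, MODERATE,
                                 baseline_abundance=100)
        res2 = project_abundance(np.full(20, -0.3), self.STD, MODERATE,
                                 baseline_abundance=200)
        np.testing.assert_allclose(res2.median, 2 * res1.median)

    def test_more_negative_beta_is_pointwise_lower(self):
        res_a = project_abundance(np.full(20, -0.3), self.STD, MODERATE)
        res_b = project_abundance(np.full(20, -0.6), self.STD, MODERATE)
        assert np.all(res_b.median <= res_a.median + 1e-12)

    def test_extinction_is_absorbing(self):
        # enormous negative effect drives abundance to zero, where it stays
        res = project_abundance(np.full(5, -200.0), self.STD, MODERATE)
        assert res.median.min() == 0.0
        k0 = int(np.argmax(res.median == 0.0))
        assert np.all(res.median[k0:] == 0.0)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            project_abundance(np.empty(0), self.STD, MODERATE)


class TestTurningPoint:
    STD = (1.2, 0.5)

    def test_monotone_trajectory_has_none(self):
        res = project_abundance(np.full(20, 0.5), self.STD, MODERATE)
        assert turning_point(res, MODERATE) is None

    def test_crossing_year_solves_pathway_equation(self):
        res = project_abundance(np.full(50, -0.44), self.STD, MODERATE)
        year, dhd = turning_point(res, MODERATE)
        assert year == 2005
        assert dhd == pytest.approx(1.2)

    def test_slow_turns_before_fast(self):
        slow, fast = DEFAULT_PATHWAYS[0], DEFAULT_PATHWAYS[2]
        beta = np.full(50, -0.44)
        y_slow, _ = turning_point(project_abundance(beta, self.STD, slow), slow)
        y_fast, _ = turning_point(project_abundance(beta, self.STD, fast), fast)
        assert y_slow < y_fast


class TestCounterfactual:
    def test_zero_observed_pressure_gives_zero_difference(self, small_fit, small_inputs):
        """Populations whose scenario covariates already sit at raw zero have a
        draw-wise zero difference."""
        import dataclasses

        inputs = dataclasses.replace(small_inputs, X=small_inputs.X.copy())
        j = small_inputs.terms.index("primary_land_loss")
        inputs.X[:10, j] = 0.0
        # recompute interactions involving the zeroed parent
        for t in inputs.terms:
            if ":" in t and "primary_land_loss" in t.split(":"):
                a, b = t.split(":")
                ja, jb = inputs.terms.index(a), inputs.terms.index(b)
                inputs.X[:10, inputs.terms.index(t)] = (
                    inputs.X[:10, ja] * inputs.X[:10, jb])
        sc = ScenarioSpec("no_habitat_loss", ("primary_land_loss",))
        res = counterfactual_diff(small_fit, inputs, sc)
        np.testing.assert_allclose(res["draws"][:, :10], 0.0, atol=1e-12)

    def test_sign_oracle_under_negative_beta(self, small_fit, small_inputs):
        """With a negative coefficient and positive observed pressure, removing
        the pressure must raise predicted rates."""
        import dataclasses

        from carnitrend.model import PosteriorSamples

        inputs = dataclasses.replace(small_inputs, X=small_inputs.X.copy())
        j = small_inputs.terms.index("primary_land_loss")
        inputs.X[:, j] = np.abs(inputs.X[:, j]) + 0.1  # pressure present everywhere
        samples = small_fit
        forced_b = samples.b.copy()
        forced_b[:, :, j] = -0.8
        forced = dataclasses.replace(samples, b=forced_b, gamma=np.ones_like(samples.gamma))
        res = counterfactual_diff(forced, inputs,
                                  ScenarioSpec("s", ("primary_land_loss",)))
        # interactions with the pressure muddy single populations; the pooled
        # effect of removing a harmful pressure must be positive
        assert res["pooled"]["median"] > 0

    def test_additivity_over_disjoint_scenarios(self, small_fit, small_inputs):
        """Zeroing two disjoint covariate sets (no shared interactions) adds."""
        a = counterfactual_diff(small_fit, small_inputs,
                                ScenarioSpec("a", ("governance",)))
        b = counterfactual_diff(small_fit, small_inputs,
                                ScenarioSpec("b", ("body_mass",)))
        ab = counterfactual_diff(small_fit, small_inputs,
                                 ScenarioSpec("ab", ("governance", "body_mass")))
        np.testing.assert_allclose(ab["draws"], a["draws"] + b["draws"], atol=1e-10)

    def test_null_coefficient_gives_null_difference(self, small_fit, small_inputs):
        """A covariate with beta == 0 in every draw contributes nothing."""
        import dataclasses

        j = small_inputs.terms.index("baseline_drought")
        forced_b = small_fit.b.copy()
        forced_b[:, :, j] = 0.0
        forced_g = small_fit.gamma.copy()
        forced_g[:, :, j] = 0.0
        forced = dataclasses.replace(small_fit, b=forced_b, gamma=forced_g)
        res = counterfactual_diff(forced, small_inputs,
                                  ScenarioSpec("null", ("baseline_drought",)))
        np.testing.assert_allclose(res["draws"], 0.0, atol=1e-12)

    def test_unknown_scenario_covariate_rejected(self, small_fit, small_inputs):
        with pytest.raises(ValueError, match="not in the model"):
            counterfactual_diff(small_fit, small_inputs,
                                ScenarioSpec("bad", ("nope",)))
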