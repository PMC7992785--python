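"""PSA: moment fitting, reproducible sampling, pipeline propagation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nashburden import (
    HealthState,
    InfeasibleMomentsError,
    PSAConfig,
    fit_distribution,
    run_psa,
    sample_parameter_set,
)
from nashburden.psa_stage import summarize


def _with_econ(ps, **kw):
    return ps.replace(econ=dataclasses.replace(ps.econ, **kw))


@pytest.fixture(scope="module")
def short_horizon_ps(base_ps):
    """Base case truncated to a 15-cycle horizon to keep PSA loops quick."""
    return _with_econ(base_ps, horizon_age=min(
        a for a in base_ps.entry_ages.values()) + 15)


class TestFitDistribution:
    def test_beta_moment_inversion(self):
        """Published F0->F1 moments: mean 0.090, se 0.026."""
        kind, a, b = fit_distribution(0.090, 0.026, "beta")
        assert kind == "beta"
        assert a / (a + b) == pytest.approx(0.090)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(0.026 ** 2)

    def test_gamma_moment_inversion(self):
        """Published cirrhosis cost moments: mean 2121, se 271."""
        kind, shape, scale = fit_distribution(2121, 271, "gamma")
        assert kind == "gamma"
        assert shape * scale == pytest.approx(2121)
        assert shape * scale ** 2 == pytest.approx(271 ** 2)

    def test_zero_se_is_point_mass(self):
        assert fit_distribution(0.5, 0.0, "beta") == ("point", 0.5)

    @pytest.mark.parametrize("mean,se", [(0.0, 0.1), (1.0, 0.1), (0.5, 0.6)])
    def test_infeasible_beta_moments_rejected(self, mean, se):
        with pytest.raises(InfeasibleMomentsError):
            fit_distribution(mean, se, "beta")

    def test_infeasible_gamma_moments_rejected(self):
        with pytest.raises(InfeasibleMomentsError):
            fit_distribution(-5.0, 1.0, "gamma")


class TestSampleParameterSet:
    def test_same_seed_same_iteration_is_identical(self, base_ps, life_table):
        cfg = PSAConfig(n_iterations=10, seed=42)
        s1, _ = sample_parameter_set(base_ps, cfg, 3, life_table)
        s2, _ = sample_parameter_set(base_ps, cfg, 3, life_table)
        assert s1 == s2

    def test_different_iterations_differ(self, base_ps, life_table):
        cfg = PSAConfig(n_iterations=10, seed=42)
        s1, _ = sample_parameter_set(base_ps, cfg, 0, life_table)
        s2, _ = sample_parameter_set(base_ps, cfg, 1, life_table)
        assert s1 != s2

    def test_varying_nothing_returns_base_case(self, base_ps, life_table):
        cfg = PSAConfig(n_iterations=1, seed=1, vary_probabilities=False,
                        vary_prevalences=False, vary_costs=False)
        sampled, redraws = sample_parameter_set(base_ps, cfg, 0, life_table)
        assert sampled == base_ps
        assert redraws == 0

    def test_structural_constants_stay_fixed(self, base_ps, life_table):
        cfg = PSAConfig(n_iterations=1, seed=7)
        sampled, _ = sample_parameter_set(base_ps, cfg, 0, life_table)
        assert sampled.edge(HealthState.F0, HealthState.NORMAL).probability == 0.0
        for band in ((18, 39), (40, 59)):
            assert sampled.edge(HealthState.NORMAL, HealthState.F0,
                                age=band[0]).probability == \
                base_ps.edge(HealthState.NORMAL, HealthState.F0,
                             age=band[0]).probability

    def test_transplant_exit_tracks_sampled_death(self, base_ps, life_table):
        cfg = PSAConfig(n_iterations=1, seed=7)
        sampled, _ = sample_parameter_set(base_ps, cfg, 0, life_table)
        lt_exit = sampled.edge(HealthState.LT, HealthState.POST_LT).probability
        assert lt_exit == pytest.approx(1.0 - sampled.mortality.p_death_lt,
                                        abs=1e-12)

    def test_sampled_sets_pass_validation(self, base_ps, life_table):
        from nashburden import validate_parameter_set
        cfg = PSAConfig(n_iterations=1, seed=99)
        for it in range(20):
            sampled, _ = sample_parameter_set(base_ps, cfg, it, life_table)
            assert validate_parameter_set(sampled) == []

    def test_empirical_means_match_published_moments(self, base_ps,
                                                     life_table):
        """Draw means stay within 3 standard errors of the inputs."""
        cfg = PSAConfig(n_iterations=1, seed=20190301)
        n = 400
        f0f1, cc = [], []
        for it in range(n):
            s, _ = sample_parameter_set(base_ps, cfg, it, life_table)
            f0f1.append(s.edge(HealthState.F0, HealthState.F1).probability)
            cc.append(s.cost("CC").annual_cost)
        assert abs(np.mean(f0f1) - 0.090) < 3 * 0.026 / np.sqrt(n)
        assert abs(np.mean(cc) - 2121) < 3 * 271 / np.sqrt(n)


class TestRunPSA:
    def test_degenerate_psa_collapses_to_base_case(self, population,
                                                   short_horizon_ps,
                                                   life_table):
        from nashburden import run_burden
        cfg = PSAConfig(n_iterations=1, seed=5, vary_probabilities=False,
                        vary_prevalences=False, vary_costs=False)
        res = run_psa(population, short_horizon_ps, life_table, cfg)
        base = run_burden(population, short_horizon_ps, life_table)
        row = res.iterations.iloc[0]
        assert row["total_cases"] == pytest.approx(base.total_cases)
        assert row["lifetime_cost"] == pytest.approx(base.total_lifetime_cost)
        assert res.summary.loc["mean", "lifetime_cost"] == pytest.approx(
            res.summary.loc["min", "lifetime_cost"])

    def test_bit_identical_rerun(self, population, short_horizon_ps,
                                 life_table):
        cfg = PSAConfig(n_iterations=12, seed=77)
        r1 = run_psa(population, short_horizon_ps, life_table, cfg)
        r2 = run_psa(population, short_horizon_ps, life_table, cfg)
        pd.testing.assert_frame_equal(r1.iterations, r2.iterations,
                                      check_exact=True)

    def test_summaries_recomputable_from_draws(self, population,
                                               short_horizon_ps, life_table):
        cfg = PSAConfig(n_iterations=30, seed=13)
        res = run_psa(population, short_horizon_ps, life_table, cfg)
        pd.testing.assert_frame_equal(summarize(res.iterations), res.summary)
        outcomes = res.iterations.drop(columns=["iteration"])
        assert (res.summary.loc["min"] <= res.summary.loc["q25"]).all()
        assert (res.summary.loc["q25"] <= res.summary.loc["q75"]).all()
        assert (res.summary.loc["q75"] <= res.summary.loc["max"]).all()
        assert res.summary.loc["max", "lifetime_cost"] == \
            outcomes["lifetime_cost"].max()

    def test_mean_converges_to_base_case(self, population, short_horizon_ps,
                                         life_table):
        """PSA mean lifetime cost near the deterministic base case."""
        from nashburden import run_burden
        cfg = PSAConfig(n_iterations=200, seed=20190301)
        res = run_psa(population, short_horizon_ps, life_table, cfg)
        base = run_burden(population, short_horizon_ps, life_table)
        draws = res.iterations["lifetime_cost"]
        mc_err = 3 * draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - base.total_lifetime_cost) < max(
            mc_err, 0.02 * base.total_lifetime_cost)

    def test_cost_only_variance_matches_delta_method(self, population,
                                                     base_ps, life_table):
        """Costs enter linearly, so the outcome variance should match the
        first-order (delta-method) prediction from per-cost sensitivities."""
        ps = _with_econ(base_ps, horizon_age=min(
            a for a in base_ps.entry_ages.values()) + 10)
        from nashburden import run_burden
        cfg = PSAConfig(n_iterations=300, seed=99, vary_probabilities=False,
                        vary_prevalences=False, vary_costs=True)
        res = run_psa(population, ps, life_table, cfg)
        base = run_burden(population, ps, life_table).total_lifetime_cost
        var_pred = 0.0
        for c in ps.costs:
            bumped_costs = tuple(
                dataclasses.replace(k, annual_cost=k.annual_cost + 1.0)
                if k.state_group == c.state_group else k for k in ps.costs)
            sens = run_burden(population, ps.replace(costs=bumped_costs),
                              life_table).total_lifetime_cost - base
            var_pred += (sens * c.se) ** 2
        var_obs = res.iterations["lifetime_cost"].var()
        assert var_obs == pytest.approx(var_pred, rel=0.2)

    def test_invalid_iteration_count_rejected(self):
        with pytest.raises(ValueError):
            PSAConfig(n_iterations=0)
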