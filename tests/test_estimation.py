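"""Likelihood, MLE, profile intervals and likelihood-ratio comparisons."""

import numpy as np
import pytest
from scipy import integrate

from fatality_window import (
    Cohort,
    FitConfig,
    JoinPointParams,
    NoEventsError,
    fit_mle,
    fixed_value_test,
    log_likelihood,
    overall_test,
    parameter_equality_test,
    profile_ci,
)
from fatality_window.model import hazard_value
from fatality_window.simulate import generate_cohort, model_exact_cohort, single_stratum_config

from conftest import random_cohort


def quadrature_loglik(params, cohort):
    """Independent per-subject oracle: numerically integrate the hazard."""
    total = 0.0
    for t, e in zip(cohort.time, cohort.event):
        H, _ = integrate.quad(
            lambda s: hazard_value(params, s),
            params.origin,
            t,
            points=[min(params.phase_shift, t)],
        )
        total += (np.log(hazard_value(params, t)) if e else 0.0) - H
    return total


class TestLogLikelihood:
    def test_single_censored_constant_hazard(self):
        p = JoinPointParams(2e-4, 2e-4, 30.0)
        c = Cohort(np.array([103.0]), np.array([False]))
        assert log_likelihood(p, c) == pytest.approx(-2e-4 * 100.0, rel=1e-12)

    def test_single_event_matches_quadrature(self, overall_params):
        c = Cohort(np.array([17.0]), np.array([True]))
        assert log_likelihood(overall_params, c) == pytest.approx(
            quadrature_loglik(overall_params, c), abs=1e-10
        )

    def test_additivity_over_partition(self, overall_params):
        rng = np.random.default_rng(11)
        c = random_cohort(rng, n=300)
        half = c.n // 2
        parts = [
            Cohort(c.time[:half], c.event[:half]),
            Cohort(c.time[half:], c.event[half:]),
        ]
        assert log_likelihood(overall_params, c) == pytest.approx(
            sum(log_likelihood(overall_params, p) for p in parts), rel=1e-12
        )

    def test_matches_quadrature_oracle_per_subject(self, overall_params):
        rng = np.random.default_rng(5)
        c = random_cohort(rng, n=150)
        ours = log_likelihood(overall_params, c)
        ref = quadrature_loglik(overall_params, c)
        assert abs(ours - ref) <= 1e-8 * c.n

    def test_rejects_times_before_origin(self, overall_params):
        c = Cohort(np.array([1.0, 50.0]), np.array([True, False]))
        with pytest.raises(ValueError, match="origin"):
            log_likelihood(overall_params, c)


class TestFitMLE:
    def test_recovers_simulated_truth(self, overall_params):
        cfg = single_stratum_config(overall_params, n=50000, seed=90210)
        _, truth = generate_cohort(cfg)
        fit = fit_mle(model_exact_cohort(truth, cfg))
        assert abs(fit.params.phase_shift - 23.8) <= 3.0
        assert fit.params.acute_rate == pytest.approx(overall_params.acute_rate, rel=0.10)
        assert fit.params.background_rate == pytest.approx(
            overall_params.background_rate, rel=0.10
        )
        assert fit.converged and not fit.boundary_flag

    def test_constant_hazard_truth_sets_boundary_flag(self):
        p = JoinPointParams(2.5e-4, 2.5e-4, 40.0)
        cfg = single_stratum_config(p, n=20000, seed=3)
        _, truth = generate_cohort(cfg)
        fit = fit_mle(model_exact_cohort(truth, cfg))
        # the change-point MLE may absorb a short noise spike near the
        # origin, but the flag must fire and the plateau must match truth
        assert fit.boundary_flag
        assert fit.params.background_rate == pytest.approx(2.5e-4, rel=0.15)

    def test_duplicated_cohort_same_estimates_double_loglik(self, medium_sim):
        c = medium_sim["exact"]
        dup = Cohort(np.concatenate([c.time, c.time]), np.concatenate([c.event, c.event]))
        f1, f2 = fit_mle(c), fit_mle(dup)
        assert f2.params.phase_shift == pytest.approx(f1.params.phase_shift, abs=0.05)
        assert f2.params.acute_rate == pytest.approx(f1.params.acute_rate, rel=1e-4)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-6)

    def test_no_events_raises(self):
        c = Cohort(np.full(50, 180.0), np.zeros(50, dtype=bool))
        with pytest.raises(NoEventsError):
            fit_mle(c)

    def test_all_events_sets_warning(self):
        rng = np.random.default_rng(1)
        c = Cohort(rng.uniform(3.5, 170, size=200), np.ones(200, dtype=bool))
        fit = fit_mle(c)
        assert fit.warnings

    def test_row_order_invariance(self, medium_sim):
        c = medium_sim["exact"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(c.n)
        f1 = fit_mle(c)
        f2 = fit_mle(Cohort(c.time[perm], c.event[perm]))
        assert f1.params.phase_shift == pytest.approx(f2.params.phase_shift, abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-12)

    def test_time_unit_rescaling(self, medium_sim):
        # days -> half-days: times double, rates halve, phase shift doubles
        c = medium_sim["exact"]
        f1 = fit_mle(c)
        cfg2 = FitConfig(origin=6.0, horizon=360.0, tau_step=1.0, tau_tol=0.02)
        f2 = fit_mle(Cohort(c.time * 2.0, c.event), cfg2)
        assert f2.params.phase_shift == pytest.approx(2 * f1.params.phase_shift, rel=5e-3)
        assert f2.params.acute_rate == pytest.approx(f1.params.acute_rate / 2, rel=5e-3)
        assert f2.params.background_rate == pytest.approx(
            f1.params.background_rate / 2, rel=5e-3
        )


class TestProfileCI:
    @pytest.fixture(scope="class")
    def fit_and_cohort(self, medium_sim):
        c = medium_sim["exact"]
        return fit_mle(c), c

    @pytest.mark.parametrize("which", ["acute_rate", "background_rate", "phase_shift"])
    def test_interval_contains_mle(self, fit_and_cohort, which):
        fit, c = fit_and_cohort
        ci = profile_ci(c, fit, which)
        assert ci.lower <= getattr(fit.params, which) <= ci.upper

    def test_lrt_duality_at_boundary(self, fit_and_cohort):
        # a parameter value on the 95% CI boundary should give p close to 0.05
        fit, c = fit_and_cohort
        ci = profile_ci(c, fit, "phase_shift")
        res = fixed_value_test(c, "phase_shift", ci.upper)
        assert res.p_value == pytest.approx(0.05, abs=0.005)

    def test_halving_n_widens_interval(self, overall_params):
        widths = {}
        for n in (6000, 24000):
            cfg = single_stratum_config(overall_params, n=n, seed=555)
            _, truth = generate_cohort(cfg)
            c = model_exact_cohort(truth, cfg)
            fit = fit_mle(c)
            ci = profile_ci(c, fit, "background_rate")
            widths[n] = ci.upper - ci.lower
        assert widths[6000] > widths[24000]

    def test_unknown_parameter_rejected(self, fit_and_cohort):
        fit, c = fit_and_cohort
        with pytest.raises(ValueError):
            profile_ci(c, fit, "slope")


class TestGroupComparisons:
    def test_duplicated_levels_give_null_result(self, medium_sim):
        c = medium_sim["exact"]
        res = overall_test({"a": c, "b": c})
        assert abs(res.statistic) <= 1e-4
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_df_bookkeeping_three_levels(self, overall_params):
        cohorts = {}
        for i in range(3):
            cfg = single_stratum_config(overall_params, n=2000, seed=70 + i)
            _, truth = generate_cohort(cfg)
            cohorts[f"level{i}"] = model_exact_cohort(truth, cfg)
        res = overall_test(cohorts)
        assert res.df == 6
        eq = parameter_equality_test(cohorts, "background_rate")
        assert eq.df == 2
        assert eq.statistic >= -1e-6

    def test_detects_background_difference(self):
        pa = JoinPointParams.from_per_1000(0.90, 0.20, 25.0)
        pb = JoinPointParams.from_per_1000(0.90, 0.14, 25.0)
        cohorts = {}
        for label, p, seed in (("colon", pa, 21), ("rectal", pb, 22)):
            cfg = single_stratum_config(p, n=20000, seed=seed)
            _, truth = generate_cohort(cfg)
            cohorts[label] = model_exact_cohort(truth, cfg)
        res = parameter_equality_test(cohorts, "background_rate")
        assert res.p_value < 0.05

    def test_identical_levels_equality_p_near_one(self, medium_sim):
        c = medium_sim["exact"]
        res = parameter_equality_test({"a": c, "b": c}, "phase_shift")
        assert res.p_value > 0.9

    def test_zero_event_level_raises_with_name(self, medium_sim):
        empty = Cohort(np.full(100, 180.0), np.zeros(100, dtype=bool))
        with pytest.raises(NoEventsError, match="sparse"):
            overall_test({"ok": medium_sim["exact"], "sparse": empty})

    def test_unknown_parameter_name(self, medium_sim):
        c = medium_sim["exact"]
        with pytest.raises(ValueError):
            parameter_equality_test({"a": c, "b": c}, "join")
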