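"""Model-free hazard diagnostics: daily rates, Nelson-Aalen, late window."""

import numpy as np
import pytest
from lifelines import NelsonAalenFitter

from fatality_window import (
    Cohort,
    cumulative_hazard,
    daily_hazard,
    late_window_rate,
    nelson_aalen,
    peak_day,
)
from fatality_window.simulate import generate_cohort, model_exact_cohort, single_stratum_config

from conftest import random_cohort


class TestDailyHazard:
    def test_toy_arithmetic(self):
        # 10 subjects at risk on day 3, 1 death that day -> 100 per 1000
        time = np.array([3.0] + [20.0] * 9)
        event = np.array([True] + [False] * 9)
        series = daily_hazard(Cohort(time, event), (3, 5))
        row = series.set_index("day").loc[3]
        assert row["at_risk"] == 10 and row["deaths"] == 1
        assert row["rate_per_1000"] == pytest.approx(100.0)

    def test_recount_oracle(self):
        rng = np.random.default_rng(13)
        c = random_cohort(rng, n=400, horizon=40)
        series = daily_hazard(c, (0, 45)).set_index("day")
        day_of = np.floor(c.time).astype(int)
        for day in range(0, 46):
            at_risk = int(np.sum(c.time >= day))
            deaths = int(np.sum(c.event & (day_of == day)))
            assert series.loc[day, "at_risk"] == at_risk
            assert series.loc[day, "deaths"] == deaths

    def test_no_deaths(self):
        c = Cohort(np.full(30, 180.0), np.zeros(30, dtype=bool))
        series = daily_hazard(c, (0, 180))
        assert (series["rate"] == 0).all()
        assert (series["at_risk"] == 30).all()

    def test_empty_day_is_undefined_not_zero(self):
        c = Cohort(np.array([5.0]), np.array([True]))
        series = daily_hazard(c, (0, 10)).set_index("day")
        assert np.isnan(series.loc[8, "rate"])

    def test_deaths_conserved(self, medium_sim):
        c = medium_sim["exact"]
        series = daily_hazard(c, (0, 180))
        assert series["deaths"].sum() == c.n_events

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            daily_hazard(Cohort(np.array([]), np.array([], dtype=bool)), (0, 10))


class TestPeakDay:
    def test_strictly_decreasing_from_origin(self):
        time = np.concatenate([np.full(4, 3.0), np.full(2, 4.0), np.full(200, 60.0)])
        event = np.concatenate([np.ones(6, dtype=bool), np.zeros(200, dtype=bool)])
        series = daily_hazard(Cohort(time, event), (3, 30))
        primary, tied = peak_day(series)
        assert primary == 3 and tied == {3}

    def test_tie_rule_earliest_primary(self):
        time = np.concatenate([np.full(3, 4.0), np.full(3, 5.0), np.full(94, 60.0)])
        event = np.concatenate([np.ones(6, dtype=bool), np.zeros(94, dtype=bool)])
        series = daily_hazard(Cohort(time, event), (3, 30))
        # 3/100 on day 4, then 3/97 on day 5: not tied; force equal risk sets
        series.loc[series["day"] == 5, ["deaths", "at_risk", "rate"]] = [3, 100, 0.03]
        series.loc[series["day"] == 4, ["deaths", "at_risk", "rate"]] = [3, 100, 0.03]
        primary, tied = peak_day(series, (4, 10))
        assert primary == 4 and tied == {4, 5}

    def test_simulated_peak_near_origin(self, overall_params):
        hits = 0
        for rep in range(10):
            cfg = single_stratum_config(overall_params, n=100000, seed=900 + rep)
            table, truth = generate_cohort(cfg)
            c = model_exact_cohort(truth, cfg)
            primary, _ = peak_day(daily_hazard(c, (3, 180)))
            hits += 3 <= primary <= 6
        assert hits >= 9

    def test_all_undefined_window_rejected(self):
        c = Cohort(np.array([5.0]), np.array([True]))
        series = daily_hazard(c, (0, 20))
        with pytest.raises(ValueError):
            peak_day(series, (10, 20))


class TestNelsonAalen:
    def test_hand_computed_toy(self):
        # 4 subjects: death day 3 (4 at risk), censor day 4, death day 5
        # (2 left at risk) -> 1/4 then 1/4 + 1/2; lifelines agrees
        c = Cohort(np.array([3.0, 4.0, 5.0, 10.0]), np.array([True, False, True, False]))
        series = nelson_aalen(c, 10).set_index("day")
        assert series.loc[3, "cum_hazard"] == pytest.approx(0.25)
        assert series.loc[4, "cum_hazard"] == pytest.approx(0.25)
        assert series.loc[5, "cum_hazard"] == pytest.approx(0.75)

    def test_no_events_flat_zero_degenerate_ci(self):
        c = Cohort(np.full(20, 60.0), np.zeros(20, dtype=bool))
        series = nelson_aalen(c, 60)
        assert (series["cum_hazard"] == 0).all()
        assert (series["ci_low"] == 0).all() and (series["ci_high"] == 0).all()

    def test_monotone_with_ordered_bounds(self, medium_sim):
        series = nelson_aalen(medium_sim["exact"], 180)
        assert (series["cum_hazard"].diff().dropna() >= 0).all()
        pos = series["cum_hazard"] > 0
        assert (series.loc[pos, "ci_low"] <= series.loc[pos, "cum_hazard"]).all()
        assert (series.loc[pos, "cum_hazard"] <= series.loc[pos, "ci_high"]).all()

    def test_agreement_with_lifelines(self):
        rng = np.random.default_rng(99)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        for _ in range(25):
            c = random_cohort(rng, n=rng.integers(20, 300), horizon=50)
            if c.n_events == 0:
                continue
            ours = nelson_aalen(c, 55).set_index("day")["cum_hazard"]
            naf.fit(c.time, c.event)
            ref = naf.cumulative_hazard_["NA_estimate"]
            for day in sorted(set(np.floor(c.time[c.event]).astype(int))):
                assert abs(ours.loc[day] - ref.loc[float(day)]) <= 1e-10

    def test_converges_to_model_cumulative_hazard(self, overall_params):
        sups = {}
        for n in (10000, 100000):
            cfg = single_stratum_config(overall_params, n=n, seed=31)
            _, truth = generate_cohort(cfg)
            series = nelson_aalen(model_exact_cohort(truth, cfg), 180)
            sub = series[series["day"] >= 3]
            model_H = np.asarray(cumulative_hazard(overall_params, sub["day"].to_numpy(float)))
            sups[n] = np.max(np.abs(sub["cum_hazard"].to_numpy() - model_H))
        assert sups[100000] < sups[10000]

    def test_model_within_pointwise_band(self, medium_sim, overall_params):
        series = nelson_aalen(medium_sim["exact"], 180)
        sub = series[(series["day"] >= 4) & (series["cum_hazard"] > 0)]
        model_H = np.asarray(cumulative_hazard(overall_params, sub["day"].to_numpy(float)))
        inside = (sub["ci_low"].to_numpy() <= model_H) & (model_H <= sub["ci_high"].to_numpy())
        assert inside.mean() >= 0.90


class TestLateWindowRate:
    def test_ratio_arithmetic(self):
        # 500 person-days of exposure per subject pair; 2 deaths in window
        time = np.array([280.0, 280.0, 360.0, 360.0])
        event = np.array([True, True, False, False])
        fit = late_window_rate(Cohort(time, event), (180.0, 360.0))
        assert fit.person_days == pytest.approx(2 * 100.0 + 2 * 180.0)
        assert fit.rate_per_1000 == pytest.approx(2.0 / 560.0 * 1000.0)

    def test_constant_late_hazard_not_rejected(self, overall_params):
        rejections = 0
        for rep in range(20):
            cfg = single_stratum_config(overall_params, n=20000, seed=4000 + rep, horizon=360.0)
            _, truth = generate_cohort(cfg)
            fit = late_window_rate(model_exact_cohort(truth, cfg))
            rejections += not fit.approximately_constant
        assert rejections <= 4

    def test_rising_late_hazard_detected(self):
        # plant a 3x jump at day 270: the two-segment LRT should notice
        rng = np.random.default_rng(8)
        n = 30000
        t1 = 180 + rng.exponential(1 / 2e-4, size=n)
        jump = t1 > 270
        t = np.where(jump, 270 + rng.exponential(1 / 6e-4, size=n), t1)
        event = t <= 360
        fit = late_window_rate(Cohort(np.minimum(t, 360.0), event), (180.0, 360.0))
        assert not fit.approximately_constant

    def test_no_person_time_rejected(self):
        c = Cohort(np.array([100.0]), np.array([False]))
        with pytest.raises(ValueError):
            late_window_rate(c, (180.0, 360.0))
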