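"""Trend OLS, seasonal t test, outing attendance, weekday baselines."""

import math
from datetime import date, time, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from routinesense import (OutingSchedule, TemperatureSeries, attendance,
                          deviation, nightly_interval_metric, ols_trend,
                          pooled_ttest, select_extreme_days, weekday_baseline)
from routinesense.change_detection import BaselineProfile, seasonal_comparison
from routinesense.cleaning import DailyCountSeries
from routinesense.exceptions import (ColdStartError, SingularDesignError,
                                     UndefinedStatisticError)

from conftest import make_log, motion, power


def day_series(values, start=date(2014, 1, 1)):
    idx = [start + timedelta(days=i) for i in range(len(values))]
    return DailyCountSeries(pd.Series([float(v) for v in values], index=idx))


def temp_series(values, start=date(2014, 1, 1)):
    idx = [start + timedelta(days=i) for i in range(len(values))]
    return TemperatureSeries(pd.Series([float(v) for v in values], index=idx))


class TestOlsTrend:
    def test_noise_free_slope_exact(self):
        n = 30
        y = day_series([2 + 3 * d for d in range(n)])
        temp = temp_series([20.0] * n)  # constant -> dropped
        res = ols_trend(y, temp)
        assert res.beta_day == pytest.approx(3.0, abs=1e-10)
        assert res.beta_temp is None

    def test_constant_response_zero_slopes(self):
        rng = np.random.default_rng(0)
        n = 30
        y = day_series([5.0] * n)
        temp = temp_series(20 + rng.normal(0, 3, n))
        res = ols_trend(y, temp)
        assert res.beta_day == pytest.approx(0.0, abs=1e-12)
        assert res.beta_temp == pytest.approx(0.0, abs=1e-12)

    def test_collinear_design_raises(self):
        n = 20
        y = day_series(range(n))
        temp = temp_series(range(n))  # t_max == day index
        with pytest.raises(SingularDesignError):
            ols_trend(y, temp)

    def test_too_few_days(self):
        with pytest.raises(UndefinedStatisticError):
            ols_trend(day_series([1, 2, 3]), temp_series([20, 21, 22]))

    def test_monte_carlo_ci_coverage(self):
        """Known generator y = 2 + 0.06 d + 0.5 t + N(0, 3): the 99% CI for
        the day slope covers 0.06 in at least 95 of 100 replicates."""
        from scipy.stats import t as t_dist

        n, hits = 180, 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            t = 24 + 8 * np.sin(2 * np.pi * np.arange(n) / 365) + rng.normal(0, 2, n)
            y = 2 + 0.06 * np.arange(n) + 0.5 * t + rng.normal(0, 3, n)
            res = ols_trend(day_series(y), temp_series(t))
            se = (res.conf_int_day[1] - res.conf_int_day[0]) / (
                2 * t_dist.ppf(0.975, n - 3))
            half99 = se * t_dist.ppf(0.995, n - 3)
            if abs(res.beta_day - 0.06) <= half99:
                hits += 1
        assert hits >= 95


class TestNightlyIntervals:
    def test_median_gap(self):
        log = make_log([motion("2014-01-01T23:00:00", "bedroom"),
                        motion("2014-01-01T23:10:00", "bedroom"),
                        motion("2014-01-01T23:30:00", "bedroom")])
        s = nightly_interval_metric(log, "bedroom")
        assert s.series.loc[date(2014, 1, 1)] == 15.0

    def test_single_firing_missing(self):
        log = make_log([motion("2014-01-01T23:30:00", "bedroom"),
                        motion("2014-01-02T10:00:00", "bedroom")])
        s = nightly_interval_metric(log, "bedroom")
        assert math.isnan(s.series.loc[date(2014, 1, 1)])

    def test_equal_spacing_and_midnight_wrap(self):
        rows = [motion(f"2014-01-01T23:{m:02d}:00", "bedroom") for m in (0, 5, 10)]
        rows += [motion("2014-01-02T00:05:00", "bedroom"),
                 motion("2014-01-02T05:00:00", "bedroom")]
        s = nightly_interval_metric(log := make_log(rows), "bedroom")
        # gaps within the same night: 5, 5, 55, 295 -> median 30
        assert s.series.loc[date(2014, 1, 1)] == 30.0


class TestExtremeDays:
    def test_order_statistics_oracle(self):
        temp = temp_series(range(1, 101))
        cold, hot = select_extreme_days(temp, 0.25)
        assert {temp[d] for d in cold} <= set(range(1, 27))
        assert {temp[d] for d in hot} >= set(range(76, 101)) or len(hot) >= 25
        assert len(cold) >= 25 and len(hot) >= 25
        assert not cold & hot

    def test_constant_temperature_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            select_extreme_days(temp_series([20] * 30), 0.25)

    def test_quantile_bounds(self):
        with pytest.raises(ValueError):
            select_extreme_days(temp_series(range(10)), 0.5)


class TestPooledTTest:
    def test_identical_samples(self):
        res = pooled_ttest([3, 4, 5], [3, 4, 5])
        assert res.t == 0.0 and res.p == 1.0

    def test_closed_form_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = pooled_ttest(a, b)
        # textbook pooled formula, coded independently
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_exp = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.t == pytest.approx(t_exp, abs=1e-10)
        assert res.df == 4

    def test_df_convention_matches_printed_subscript(self):
        rng = np.random.default_rng(0)
        res = pooled_ttest(rng.normal(34, 7, 47), rng.normal(41, 10, 47))
        assert res.df == 92

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12),
           st.lists(st.floats(-50, 50), min_size=2, max_size=12))
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_formula_on_random_samples(self, a, b):
        a, b = np.round(a, 6), np.round(b, 6)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        res = pooled_ttest(a, b)
        assert res.df == na + nb - 2
        if sp2 > 0:
            t_exp = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
            assert res.t == pytest.approx(t_exp, abs=1e-10)

    def test_zero_variance_unequal_means(self):
        res = pooled_ttest([1, 1], [2, 2])
        assert math.isinf(res.t) and res.p == 0.0


class TestWeekdayBaseline:
    def _weekly_log(self, n_weeks=5, hour=9, weekday_date=date(2014, 1, 5)):
        rows = []
        for k in range(n_weeks):
            d = weekday_date + timedelta(weeks=k)
            rows.append(motion(pd.Timestamp(d) + pd.Timedelta(hours=hour), "lounge"))
        return make_log(rows, first_day=weekday_date,
                        last_day=weekday_date + timedelta(weeks=n_weeks - 1))

    def test_identical_weeks_zero_sd(self):
        log = self._weekly_log(5)
        day = date(2014, 1, 5) + timedelta(weeks=4)
        base = weekday_baseline(log, day, "lounge", "motion", window_weeks=4)
        assert base.n == 4
        assert base.mean[9] == 1.0 and (base.sd == 0).all()

    def test_day_under_test_excluded(self):
        log = self._weekly_log(5)
        day = date(2014, 1, 5) + timedelta(weeks=4)
        base = weekday_baseline(log, day, "lounge", "motion", window_weeks=4)
        assert day not in base.contributing_days

    def test_window_cap(self):
        log = self._weekly_log(8)
        day = date(2014, 1, 5) + timedelta(weeks=7)
        base = weekday_baseline(log, day, "lounge", "motion", window_weeks=4)
        assert base.n == 4

    def test_cold_start(self):
        log = self._weekly_log(2)
        with pytest.raises(ColdStartError):
            weekday_baseline(log, date(2014, 1, 12), "lounge", "motion",
                             window_weeks=4)


class TestDeviation:
    def test_identical_day_scores_zero(self):
        base = BaselineProfile(mean=np.full(24, 3.0), sd=np.zeros(24),
                               weekday=0, contributing_days=())
        rep = deviation(np.full(24, 3.0), base)
        assert rep.score == 0.0 and rep.level == "none"

    def test_score_zero_iff_equal_to_mean(self):
        base = BaselineProfile(mean=np.arange(24, dtype=float), sd=np.ones(24),
                               weekday=0, contributing_days=())
        bumped = np.arange(24, dtype=float)
        bumped[3] += 1
        assert deviation(np.arange(24, dtype=float), base).score == 0.0
        assert deviation(bumped, base).score > 0.0

    def test_levels_monotone_in_score(self):
        base = BaselineProfile(mean=np.zeros(24), sd=np.zeros(24),
                               weekday=0, contributing_days=())
        assert deviation(np.full(24, 0.5), base).level == "none"
        assert deviation(np.full(24, 1.0), base).level == "low"
        assert deviation(np.full(24, 2.0), base).level == "high"


class TestAttendance:
    SCHEDULE = OutingSchedule("bridge club", {0, 3, 5}, time(13, 0), time(17, 0))

    def test_silent_window_is_away(self):
        # 2014-01-06 is a Monday; only morning movement
        log = make_log([motion("2014-01-06T09:00:00", "lounge"),
                        motion("2014-01-06T18:00:00", "lounge")])
        series = attendance(log, self.SCHEDULE)
        assert list(series.table["away"]) == [True]

    def test_in_window_movement_is_home(self):
        log = make_log([motion("2014-01-06T14:00:00", "lounge")])
        assert list(attendance(log, self.SCHEDULE).table["away"]) == [False]

    def test_power_events_ignored(self):
        log = make_log([motion("2014-01-06T09:00:00", "lounge"),
                        power("2014-01-06T14:00:00", "television", 0.5, "lounge")])
        assert list(attendance(log, self.SCHEDULE).table["away"]) == [True]

    def test_empty_schedule_occasions(self):
        log = make_log([motion("2014-01-06T09:00:00", "lounge")])
        sched = OutingSchedule("never", {6}, time(13, 0), time(17, 0))
        assert len(attendance(log, sched).table) == 0

    def test_resumption_change_point_detected(self):
        """Attendance 0.2 for 4 weeks then 0.9: the rolling rate crosses 0.5
        within +/-2 weeks of the change point (bereavement-recovery pattern)."""
        rng = np.random.default_rng(42)
        start = date(2014, 1, 6)  # Monday
        rows = []
        change = start + timedelta(weeks=4)
        for i in range(12 * 7):
            d = start + timedelta(days=i)
            rows.append(motion(pd.Timestamp(d) + pd.Timedelta(hours=9), "lounge"))
            if d.weekday() in self.SCHEDULE.weekdays:
                p = 0.2 if d < change else 0.9
                if rng.uniform() >= p:  # stayed home: in-window movement
                    rows.append(motion(pd.Timestamp(d) + pd.Timedelta(hours=14),
                                       "lounge"))
        series = attendance(make_log(rows), self.SCHEDULE)
        rate = series.rolling_rate(window=6)
        crossed = [d for d, r in rate.items() if r > 0.5]
        assert crossed, "rolling attendance never crossed 0.5"
        first = min(crossed)
        assert abs((first - change).days) <= 14


def test_seasonal_comparison_end_to_end():
    """Hot days generated with a higher daily mean: the pooled test recovers
    the direction with its df equal to n_cold + n_hot - 2."""
    rng = np.random.default_rng(7)
    n = 180
    t = 24 + 10 * np.sin(2 * np.pi * np.arange(n) / 365) + rng.normal(0, 2, n)
    y = 30 + 0.7 * (t - t.mean()) + rng.normal(0, 3, n)
    res = seasonal_comparison(day_series(y), temp_series(t), 0.25)
    assert res.mean_hot > res.mean_cold
    assert res.df == res.n_cold + res.n_hot - 2
    assert res.p < 0.01
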