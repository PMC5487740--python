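"""Simulator determinism, conservation, injections, archetype contrasts."""

import io
from datetime import date, time, timedelta

import numpy as np
import pandas as pd
import pytest

from routinesense import (CleaningConfig, RoutineWindow, adherence,
                          binarize_power, classify_gaps, daily_counts,
                          make_temperature, ols_trend, write_event_log)
from routinesense.exceptions import ConfigError
from routinesense.synthetic_data import (PRESETS, ActivitySpec, ArtifactSpec,
                                         ResidentProfile, inject_illness,
                                         inject_trend, simulate)

KETTLE_DAILY = ActivitySpec("breakfast", "kitchen", "kettle", time(7, 30),
                            jitter_sd_min=0, adherence_p=1.0, burst_mean=0)


def lean_profile(**kwargs) -> ResidentProfile:
    defaults = dict(activities=(KETTLE_DAILY,), background={})
    defaults.update(kwargs)
    return ResidentProfile(**defaults)


class TestSimulate:
    def test_degenerate_profile_is_deterministic_breakfast(self):
        """sigma=0, p=1, no background: exactly one kettle sample per day at
        07:30 and downstream adherence 100%."""
        log, truth = simulate(lean_profile(), ArtifactSpec(), n_days=30, seed=5)
        kettle = log.filter(sensor_kind="power", channel="kettle")
        assert len(kettle) == 30
        assert (kettle["timestamp"].dt.strftime("%H:%M").unique() == ["07:32"]).all() or \
            (kettle["timestamp"].dt.hour == 7).all()
        clean = binarize_power(log, CleaningConfig())
        res = adherence(clean, RoutineWindow(channel="kettle"))
        assert res.adherence_pct == 100.0
        assert res.partition.with_data == 30

    def test_reproducible_for_fixed_seed(self):
        profile, artifacts = PRESETS["elizabeth"]()
        a, _ = simulate(profile, artifacts, n_days=20, seed=9)
        b, _ = simulate(profile, artifacts, n_days=20, seed=9)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        write_event_log(a, buf_a)
        write_event_log(b, buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_seed_changes_stream(self):
        profile, artifacts = PRESETS["elizabeth"]()
        a, _ = simulate(profile, artifacts, n_days=20, seed=9)
        b, _ = simulate(profile, artifacts, n_days=20, seed=10)
        assert not a.events.equals(b.events)

    def test_adding_sensor_does_not_perturb_other_streams(self):
        base = lean_profile(background={"lounge": np.full(24, 1.0)})
        more = lean_profile(background={"lounge": np.full(24, 1.0),
                                        "bathroom": np.full(24, 0.5)})
        log_a, _ = simulate(base, ArtifactSpec(), n_days=15, seed=3)
        log_b, _ = simulate(more, ArtifactSpec(), n_days=15, seed=3)
        lounge_a = log_a.filter(room="lounge")["timestamp"]
        lounge_b = log_b.filter(room="lounge")["timestamp"]
        assert list(lounge_a) == list(lounge_b)

    def test_activity_occurrence_matches_binomial_rate(self):
        """Bursts per ActivitySpec approximate p x eligible days."""
        p = 0.7
        act = ActivitySpec("breakfast", "kitchen", "kettle", time(7, 30),
                           jitter_sd_min=5, adherence_p=p, burst_mean=0)
        n_days, total, reps = 120, 0, 5
        for s in range(reps):
            _, truth = simulate(lean_profile(activities=(act,)), ArtifactSpec(),
                                n_days=n_days, seed=100 + s)
            total += sum("breakfast" in a for a in truth.activities.values())
        n = n_days * reps
        se = (p * (1 - p) / n) ** 0.5
        assert abs(total / n - p) < 3 * se

    def test_ground_truth_coupling(self):
        """Every truth activity has a matching in-log appliance sample."""
        log, truth = simulate(lean_profile(), ArtifactSpec(), n_days=10, seed=2)
        kettle = log.filter(sensor_kind="power", channel="kettle")
        days_logged = set(kettle["timestamp"].dt.date)
        assert days_logged == set(truth.activities)

    def test_invalid_profile_rejected_before_generation(self):
        with pytest.raises(ConfigError):
            simulate(lean_profile(travel_blocks=((50, 100),)), ArtifactSpec(),
                     n_days=60, seed=0)
        with pytest.raises(ConfigError):
            ActivitySpec("x", "kitchen", None, time(8), adherence_p=1.5)

    def test_standby_grid_exercises_binarization(self):
        art = ArtifactSpec(standby_kwh={"kettle": 0.001})
        log, _ = simulate(lean_profile(), art, n_days=5, seed=1)
        kettle = log.filter(sensor_kind="power", channel="kettle")
        assert len(kettle) == 5 * 288  # full 5-minute grid
        clean = binarize_power(log, CleaningConfig())
        assert len(clean.filter(sensor_kind="power", channel="kettle")) == 5


class TestTemperature:
    def test_degenerate_constant(self):
        t = make_temperature(50, mean=20, amplitude=0, noise_sd=0, seed=0)
        assert (t.series == 20).all()

    def test_reproducible(self):
        a = make_temperature(50, seed=4)
        b = make_temperature(50, seed=4)
        assert a.series.equals(b.series)

    def test_quantiles_bracket_envelope(self):
        t = make_temperature(365, mean=24, amplitude=8, noise_sd=0.5, seed=1)
        assert t.series.quantile(0.01) > 24 - 8 - 3
        assert t.series.quantile(0.99) < 24 + 8 + 3
        assert t.series.min() < 24 - 6 and t.series.max() > 24 + 6


class TestInjections:
    def test_travel_block_recovered_exactly(self):
        """A 14-day travel silence is recovered by gap classification with
        the exact endpoints recorded in ground truth."""
        profile = lean_profile(background={"lounge": np.full(24, 1.0)},
                               travel_blocks=((30, 14),))
        log, truth = simulate(profile, ArtifactSpec(), n_days=90, seed=6)
        clean = binarize_power(log, CleaningConfig())
        gaps = classify_gaps(clean, cfg=CleaningConfig())
        absences = [g for g in gaps if g.label == "absence"]
        assert len(truth.travel_silences) == 1
        lo, hi = truth.travel_silences[0]
        assert any(g.start == lo and g.end == hi for g in absences)
        block_days = {date(2014, 1, 1) + timedelta(days=30 + i) for i in range(14)}
        assert all(not truth.presence[d] for d in block_days)

    def test_illness_suppresses_kitchen_and_elevates_lounge(self):
        profile, artifacts = PRESETS["rupert"]()
        log, truth = simulate(profile, artifacts, n_days=42, seed=8)
        interval = (date(2014, 1, 29), date(2014, 1, 30))
        sick, truth = inject_illness(log, truth, interval, severity=0.8, seed=8)
        kitchen = daily_counts(sick, room="kitchen", sensor_kind="motion").series
        lounge = daily_counts(sick, room="lounge", sensor_kind="motion").series
        pre = [interval[0] - timedelta(weeks=k) for k in (1, 2, 3)]
        assert kitchen.loc[interval[0]] < np.mean([kitchen.loc[d] for d in pre])
        assert lounge.loc[interval[0]] > np.mean([lounge.loc[d] for d in pre])
        assert truth.illness_intervals == [interval]

    def test_zero_severity_is_identity(self):
        profile, artifacts = PRESETS["rupert"]()
        log, truth = simulate(profile, artifacts, n_days=20, seed=8)
        out, _ = inject_illness(log, truth, (date(2014, 1, 10), date(2014, 1, 11)),
                                severity=0.0, seed=8)
        assert out.events.equals(log.events)

    def test_interval_outside_span_rejected(self):
        profile, artifacts = PRESETS["rupert"]()
        log, truth = simulate(profile, artifacts, n_days=20, seed=8)
        with pytest.raises(ConfigError):
            inject_illness(log, truth, (date(2014, 2, 1), date(2014, 2, 2)))

    def test_trend_slope_recovered_on_nightly_counts(self):
        """A positive injected night slope yields a significantly positive
        OLS day coefficient on daily bedroom counts."""
        base = lean_profile(
            activities=(),
            background={"bedroom": np.array([3.0, 2.0, 2.0, 2.0, 2.0, 2.5,
                                             1.0, 0.5] + [0.3] * 15 + [2.0])})
        profile = inject_trend(base, 0.004)  # rate growth factor 1 -> 1.72
        log, truth = simulate(profile, ArtifactSpec(), n_days=180, seed=12)
        temp = truth.temperature
        y = daily_counts(log, room="bedroom", sensor_kind="motion")
        res = ols_trend(y, temp)
        assert res.beta_day > 0
        assert res.p_day < 0.001

    def test_zero_slope_profile_unchanged(self):
        base = lean_profile()
        assert inject_trend(base, 0.0) == base


class TestArchetypes:
    def test_rupert_more_adherent_than_jacqui(self, rupert_sim, jacqui_sim):
        """The rigid-routine archetype scores higher breakfast adherence than
        the travelling archetype on matched seeds."""
        rup = adherence(rupert_sim["clean"],
                        RoutineWindow(channel="microwave"), rupert_sim["gaps"])
        jac = adherence(jacqui_sim["clean"],
                        RoutineWindow(channel="kettle"), jacqui_sim["gaps"])
        assert rup.adherence_pct > jac.adherence_pct

    def test_jacqui_has_absent_days(self, jacqui_sim):
        w = RoutineWindow(channel="kettle")
        from routinesense import partition_days
        p = partition_days(jacqui_sim["clean"], w, jacqui_sim["gaps"])
        assert p.absent >= 14  # at least the 14-day travel block

    def test_routinization_contrast(self):
        from routinesense import RoutinizationAnswers, routinization_score
        elizabeth = PRESETS["elizabeth"]()[0]
        jacqui = PRESETS["jacqui"]()[0]
        assert routinization_score(RoutinizationAnswers(elizabeth.routinization)) == 100
        assert routinization_score(RoutinizationAnswers(jacqui.routinization)) == 63
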