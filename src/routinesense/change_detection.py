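"""Change detection across the four classical time-series components.

Routine change decomposes the way longitudinal data are traditionally read:

* **Trend** — slow drift (e.g. growing night restlessness): OLS of a daily
  metric on day index, controlling for daily maximum temperature so that a
  hot spell is not mistaken for decline.
* **Seasonal** — hot-vs-cold contrasts: pooled-variance two-sample t test of
  a daily metric between the coldest and hottest days.
* **Cyclical** — weekly social rhythm: scheduled outings (bridge club,
  Sunday church) detected as whole-home *absence of movement* inside the
  scheduled window, tracked as an attendance series.
* **Irregular** — acute events: a day's 24-bin profile compared against a
  same-weekday moving baseline (4-6 trailing weeks), scored as a mean
  absolute z-deviation and mapped onto two alert levels (low/high).

DST transition days artificially shift every wall-clock time by an hour, so
they are excluded from baselines by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, time, timedelta

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import ColdStartError, SingularDesignError, UndefinedStatisticError
from .cleaning import DailyCountSeries
from .profiles import CyclicalProfile, daily_bin_vector
from .sensor_io import EventLog

#: pseudo-count added to per-bin baseline SDs; stabilizes zero-variance bins
#: of sparse count data without drowning real variation
SD_EPSILON = 0.5

#: default two-level alert thresholds on the mean-|z| deviation score
THETA_LOW = 1.5
THETA_HIGH = 3.0


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily maximum temperature (deg C) keyed by local date."""

    series: pd.Series  # index: date, values: t_max

    def __post_init__(self):
        object.__setattr__(self, "series", self.series.astype(float))

    def __getitem__(self, d: date) -> float:
        return float(self.series.loc[d])

    def __len__(self):
        return len(self.series)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureSeries":
        """From a (date, t_max_c) table as read from the temperature CSV."""
        s = pd.Series(df["t_max_c"].to_numpy(),
                      index=pd.to_datetime(df["date"]).dt.date)
        return cls(s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": list(self.series.index),
                             "t_max_c": self.series.to_numpy()})


@dataclass(frozen=True)
class TrendResult:
    """Slope of a daily metric per day, with temperature controlled."""

    beta_day: float
    beta_temp: float | None
    p_day: float
    p_temp: float | None
    n: int
    response: str = ""
    conf_int_day: tuple = (np.nan, np.nan)  # 95% CI for beta_day


@dataclass(frozen=True)
class SeasonalComparison:
    """Pooled two-sample t test between cold-day and hot-day metrics."""

    mean_cold: float
    sd_cold: float
    n_cold: int
    mean_hot: float
    sd_hot: float
    n_hot: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class BaselineProfile:
    """Same-weekday reference: per-bin mean and SD over trailing weeks."""

    mean: np.ndarray  # 24
    sd: np.ndarray  # 24, population SD across contributing days
    weekday: int
    contributing_days: tuple

    @property
    def n(self) -> int:
        return len(self.contributing_days)


@dataclass(frozen=True)
class DeviationReport:
    """A day's departure from its weekday baseline, with alert level."""

    day: date
    per_bin: np.ndarray  # signed z-like deviations, 24 values
    score: float  # mean absolute deviation
    level: str  # none | low | high


@dataclass(frozen=True)
class OutingSchedule:
    """A recurring out-of-home commitment (e.g. bridge club Mon/Thu/Sat)."""

    label: str
    weekdays: frozenset  # 0=Mon .. 6=Sun
    start: time
    end: time

    def __post_init__(self):
        object.__setattr__(self, "weekdays", frozenset(self.weekdays))
        if self.start >= self.end:
            raise ValueError("outing window start must precede end")

    def occasions(self, days) -> list[date]:
        return [d for d in days if d.weekday() in self.weekdays]


@dataclass(frozen=True)
class AttendanceSeries:
    """Per-occasion away flags and in-window movement counts."""

    schedule: OutingSchedule
    table: pd.DataFrame  # columns: date, away, movement_count

    def rolling_rate(self, window: int = 6) -> pd.Series:
        """Rolling attendance (away) rate over the trailing ``window`` occasions."""
        return self.table.set_index("date")["away"].astype(float).rolling(
            window, min_periods=1).mean()


def ols_trend(y: DailyCountSeries, temp: TemperatureSeries,
              response: str = "") -> TrendResult:
    """OLS of a daily metric on [1, day index, t_max]; classical p-values.

    Missing days in ``y`` are skipped; a zero-variance temperature column is
    dropped (its coefficient is then reported as None).  Day index counts
    from the first day of the series.
    """
    s = y.series.dropna()
    days = list(s.index)
    if len(days) < 10:
        raise UndefinedStatisticError("trend needs at least 10 days of data")
    missing = [d for d in days if d not in temp.series.index]
    if missing:
        raise UndefinedStatisticError(
            f"temperature series missing {len(missing)} days (e.g. {missing[0]})")
    day_idx = np.array([(d - days[0]).days for d in days], dtype=float)
    t_max = np.array([temp[d] for d in days])
    use_temp = float(np.ptp(t_max)) > 0
    cols = {"day": day_idx}
    if use_temp:
        cols["t_max"] = t_max
    X = sm.add_constant(pd.DataFrame(cols, index=range(len(days))))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError("collinear or constant regressors")
    fit = sm.OLS(s.to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    return TrendResult(
        beta_day=float(fit.params["day"]),
        beta_temp=float(fit.params["t_max"]) if use_temp else None,
        p_day=float(fit.pvalues["day"]),
        p_temp=float(fit.pvalues["t_max"]) if use_temp else None,
        n=len(days),
        response=response,
        conf_int_day=(float(ci.loc["day", 0]), float(ci.loc["day", 1])),
    )


def nightly_interval_metric(log: EventLog, room: str,
                            night_start: time = time(23, 0),
                            night_end: time = time(6, 0)) -> DailyCountSeries:
    """Per-night median inter-firing interval (minutes) in a room.

    The night window wraps midnight and is attributed to its starting date.
    Nights with fewer than two firings yield NaN (no interval to measure).
    """
    ev = log.filter(room=room, sensor_kind="motion")
    per_night: dict[date, list] = {}
    for ts in ev["timestamp"]:
        t = ts.time()
        if t >= night_start:
            per_night.setdefault(ts.date(), []).append(ts)
        elif t < night_end:
            per_night.setdefault(ts.date() - timedelta(days=1), []).append(ts)
    days = log.span_days
    vals = []
    for d in days:
        stamps = sorted(per_night.get(d, []))
        if len(stamps) < 2:
            vals.append(np.nan)
        else:
            gaps = np.diff([s.value for s in stamps]) / 60e9  # ns -> minutes
            vals.append(float(np.median(gaps)))
    series = pd.Series(vals, index=days, dtype=float)
    out = DailyCountSeries.__new__(DailyCountSeries)
    out.series = series
    out.room, out.sensor_kind, out.channel = room, "motion", None
    return out


def select_extreme_days(temp: TemperatureSeries, q: float = 0.25):
    """Split days into the coldest and hottest q-tails by daily maximum.

    Returns (cold_days, hot_days): t_max <= q-quantile and >= (1-q)-quantile.
    Raises on degenerate series where the two tails would overlap.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    vals = temp.series
    lo = float(np.percentile(vals, 100 * q))
    hi = float(np.percentile(vals, 100 * (1 - q)))
    cold = set(vals.index[vals <= lo])
    hot = set(vals.index[vals >= hi])
    if cold & hot:
        raise UndefinedStatisticError(
            "temperature quantiles coincide; hot and cold tails overlap")
    return cold, hot


def pooled_ttest(a, b) -> SeasonalComparison:
    """Independent-samples t test with pooled variance, df = n_a + n_b - 2."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UndefinedStatisticError("each group needs at least 2 values")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float(np.inf) if a.mean() > b.mean() else float(-np.inf)
            p = 0.0
    else:
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return SeasonalComparison(
        mean_cold=float(a.mean()), sd_cold=float(a.std(ddof=1)), n_cold=len(a),
        mean_hot=float(b.mean()), sd_hot=float(b.std(ddof=1)), n_hot=len(b),
        t=t, df=df, p=p,
    )


def seasonal_comparison(y: DailyCountSeries, temp: TemperatureSeries,
                        q: float = 0.25) -> SeasonalComparison:
    """Convenience: pooled t test of a daily metric on cold vs hot days."""
    cold, hot = select_extreme_days(temp, q)
    s = y.series.dropna()
    return pooled_ttest(s[[d for d in s.index if d in cold]],
                        s[[d for d in s.index if d in hot]])


def dst_shift_days(tz_segments, spans_into_local=None) -> set:
    """Local dates on which a wall-clock offset change takes effect."""
    out = set()
    for start, off in tz_segments[1:]:
        out.add((pd.Timestamp(start) + pd.Timedelta(minutes=off)).date())
    return out


def weekday_baseline(history: EventLog, day: date, room=None, sensor_kind=None,
                     channel=None, window_weeks: int = 6,
                     exclude_days: set = frozenset()) -> BaselineProfile:
    """Same-weekday reference profile from the trailing window.

    Uses the up to ``window_weeks`` same-weekday days strictly before ``day``
    (the day under test never contributes to its own baseline), skipping
    excluded days (absences, DST shifts).  Needs >= 2 contributing days.
    """
    if not 4 <= window_weeks <= 6:
        raise ValueError("the moving window spans 4 to 6 weeks")
    first = history.first_day
    contributing = []
    for k in range(1, window_weeks + 1):
        d = day - timedelta(weeks=k)
        if first is None or d < first or d in exclude_days:
            continue
        contributing.append(d)
    if len(contributing) < 2:
        raise ColdStartError(
            f"only {len(contributing)} same-weekday days before {day}")
    vectors = np.stack([
        daily_bin_vector(history, d, room, sensor_kind, channel)
        for d in contributing
    ])
    return BaselineProfile(
        mean=vectors.mean(axis=0), sd=vectors.std(axis=0, ddof=0),
        weekday=day.weekday(), contributing_days=tuple(sorted(contributing)),
    )


def deviation(day_profile: CyclicalProfile | np.ndarray, baseline: BaselineProfile,
              day: date | None = None, theta_low: float = THETA_LOW,
              theta_high: float = THETA_HIGH,
              eps: float = SD_EPSILON) -> DeviationReport:
    """Score a day against its baseline: mean |(count - mean)/(sd + eps)|."""
    bins = day_profile.bins if isinstance(day_profile, CyclicalProfile) \
        else np.asarray(day_profile, dtype=float)
    per_bin = (bins - baseline.mean) / (baseline.sd + eps)
    score = float(np.mean(np.abs(per_bin)))
    if score >= theta_high:
        level = "high"
    elif score >= theta_low:
        level = "low"
    else:
        level = "none"
    return DeviationReport(day=day, per_bin=per_bin, score=score, level=level)


def attendance(log: EventLog, schedule: OutingSchedule,
               absence_threshold: int = 0) -> AttendanceSeries:
    """Detect attendance of scheduled outings from absence of motion.

    For each scheduled occasion, ``away`` is True iff the whole-home motion
    count inside the window is <= ``absence_threshold``.  Power events are
    ignored: appliances on standby or timers fire regardless of presence.
    """
    motion = log.filter(sensor_kind="motion")
    rows = []
    for d in schedule.occasions(log.span_days):
        lo = pd.Timestamp(d) + pd.Timedelta(hours=schedule.start.hour,
                                            minutes=schedule.start.minute)
        hi = pd.Timestamp(d) + pd.Timedelta(hours=schedule.end.hour,
                                            minutes=schedule.end.minute)
        count = int(((motion["timestamp"] >= lo)
                     & (motion["timestamp"] <= hi)).sum())
        rows.append({"date": d, "away": count <= absence_threshold,
                     "movement_count": count})
    return AttendanceSeries(schedule,
                            pd.DataFrame(rows, columns=["date", "away",
                                                        "movement_count"]))
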