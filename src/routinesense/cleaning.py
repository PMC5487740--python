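"""Cleaning raw streams: standby removal, gap classification, outlier repair.

Three preparation steps turn a localized raw log into analysis-ready data:

1. **Binarization** — appliance power samples arrive on a 5-minute grid and
   include standby draw (a television on standby still reports a few watts).
   Samples strictly above a per-channel threshold become "in use" firings
   (value 1); the rest are dropped.  Motion events pass through untouched.
2. **Gap classification** — long silences are either a genuine absence from
   home (every sensor quiet) or a sensor battery failure (one sensor quiet
   while normal movement continues elsewhere).  Gaps shorter than
   ``min_absence`` (default 24 h) are ignored: an overnight lull is normal.
3. **High-outlier repair** — visitor days and the firing spike some motion
   sensors emit just before battery death inflate daily counts.  Values above
   Q3 + k*IQR (k = 3) are replaced by the mean of the non-outlier values.
   Low values are never touched: a quiet day is a signal, not an artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .sensor_io import EventLog

HOURS_24 = timedelta(hours=24)


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds and constants for the cleaning stage.

    standby_threshold : per-channel kWh-per-sample cutoffs; a sample must
        exceed (strictly) its channel's cutoff to count as appliance use.
    default_threshold : fallback cutoff for channels not listed; None means
        unknown channels are a configuration error.
    min_absence : minimum silence to classify as absence/battery failure.
    outlier_multiplier : the k in the Q3 + k*IQR high-outlier fence.
    """

    standby_threshold: dict = field(default_factory=dict)
    default_threshold: float | None = 0.005
    min_absence: timedelta = HOURS_24
    outlier_multiplier: float = 3.0

    def __post_init__(self):
        if any(v < 0 for v in self.standby_threshold.values()):
            raise ConfigError("standby thresholds must be >= 0")
        if self.default_threshold is not None and self.default_threshold < 0:
            raise ConfigError("default threshold must be >= 0")
        if self.min_absence <= timedelta(0):
            raise ConfigError("min_absence must be positive")
        if self.outlier_multiplier <= 0:
            raise ConfigError("outlier multiplier must be positive")

    def threshold_for(self, channel: str) -> float:
        if channel in self.standby_threshold:
            return self.standby_threshold[channel]
        if self.default_threshold is None:
            raise ConfigError(f"no standby threshold for channel {channel!r}")
        return self.default_threshold


@dataclass(frozen=True)
class GapInterval:
    """A classified data gap: all-sensor absence or single-sensor failure."""

    start: pd.Timestamp
    end: pd.Timestamp
    scope: str  # all_sensors | single_sensor
    label: str  # absence | battery_failure
    sensor: tuple | None = None  # (room, kind, channel) for single_sensor

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("gap end must follow start")
        if (self.label == "absence") != (self.scope == "all_sensors"):
            raise ValueError("absence gaps are exactly the all-sensor gaps")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start

    def covers_day(self, day: date) -> bool:
        """True if the local day lies fully inside the gap."""
        day_start = pd.Timestamp(day)
        return self.start <= day_start and day_start + HOURS_24 <= self.end


@dataclass
class DailyCountSeries:
    """Per-local-day firing counts for one (room, sensor_kind, channel).

    Counts are non-negative reals: integer firings before repair, possibly a
    fractional replacement mean after.
    """

    series: pd.Series  # index: consecutive local dates; values: counts
    room: str | None = None
    sensor_kind: str | None = None
    channel: str | None = None

    def __post_init__(self):
        if (self.series < 0).any():
            raise ValueError("counts must be >= 0")

    def __len__(self):
        return len(self.series)


def binarize_power(log: EventLog, cfg: CleaningConfig) -> EventLog:
    """Replace power samples by in-use firings; drop standby samples.

    A power sample becomes one firing (value 1) at its own timestamp iff its
    value strictly exceeds the channel threshold.  Motion events are
    unchanged in number and timing.
    """
    ev = log.events
    power = ev["sensor_kind"] == "power"
    if power.any():
        thr = ev.loc[power, "channel"].map(cfg.threshold_for)
        keep_power = ev.loc[power, "value"] > thr.astype(float)
        drop_idx = ev.index[power][~keep_power]
        ev = ev.drop(index=drop_idx).copy()
        ev.loc[ev["sensor_kind"] == "power", "value"] = 1.0
    out = replace(log, events=ev.reset_index(drop=True))
    return out


def _silences(times: np.ndarray, span_start: pd.Timestamp, span_end: pd.Timestamp,
              min_gap: timedelta):
    """Maximal event-free intervals strictly over min_gap in the span.

    Strict: a silence of exactly ``min_gap`` (a daily firing 24 h apart) is
    not a gap — gaps are silences *over* the threshold.
    """
    bounds = np.concatenate(([span_start.to_datetime64()], times,
                             [span_end.to_datetime64()]))
    gap_ns = np.diff(bounds).astype("timedelta64[ns]")
    thr = np.timedelta64(int(min_gap.total_seconds() * 1e9), "ns")
    out = []
    for i in np.nonzero(gap_ns > thr)[0]:
        out.append((pd.Timestamp(bounds[i]), pd.Timestamp(bounds[i + 1])))
    return out


def classify_gaps(log: EventLog, inventory: list[tuple] | None = None,
                  cfg: CleaningConfig | None = None) -> list[GapInterval]:
    """Classify long silences as whole-home absence or sensor battery failure.

    ``inventory`` lists the installed sensors as (room, kind, channel)
    triples; it defaults to the sensors seen in the log.  An interval over
    ``cfg.min_absence`` with no event from any sensor is an absence; an
    interval where one sensor is silent while at least one other fires is a
    battery-failure gap for that sensor.  Battery-failure intervals exclude
    any overlap with absence intervals (silence during absence proves
    nothing about the sensor).
    """
    cfg = cfg or CleaningConfig()
    if inventory is not None and not inventory:
        raise ConfigError("sensor inventory is empty")
    if log.first_day is None:
        return []
    if inventory is None:
        inventory = log.sensors()
    ev = log.events
    span_start = pd.Timestamp(log.first_day)
    span_end = pd.Timestamp(log.last_day) + HOURS_24

    all_times = ev["timestamp"].to_numpy()
    absences = [
        GapInterval(a, b, "all_sensors", "absence")
        for a, b in _silences(all_times, span_start, span_end, cfg.min_absence)
    ]

    gaps: list[GapInterval] = list(absences)
    for sensor in inventory:
        room, kind, channel = sensor
        times = log.filter(room, kind, channel)["timestamp"].to_numpy()
        for a, b in _silences(times, span_start, span_end, cfg.min_absence):
            # carve out portions covered by whole-home absence
            pieces = [(a, b)]
            for ab in absences:
                pieces = [
                    p
                    for lo, hi in pieces
                    for p in ((lo, min(hi, ab.start)), (max(lo, ab.end), hi))
                    if p[1] > p[0]
                ]
            for lo, hi in pieces:
                if hi - lo <= cfg.min_absence:
                    continue
                others = (all_times >= lo.to_datetime64()) & (all_times < hi.to_datetime64())
                if others.any():  # movement elsewhere while this sensor is dark
                    gaps.append(GapInterval(lo, hi, "single_sensor",
                                            "battery_failure", sensor))
    gaps.sort(key=lambda g: (g.start, g.scope, g.sensor or ()))
    return gaps


def absent_days(gaps: list[GapInterval], days: list[date]) -> set[date]:
    """Days lying fully inside an all-sensor absence gap."""
    abs_gaps = [g for g in gaps if g.label == "absence"]
    return {d for d in days if any(g.covers_day(d) for g in abs_gaps)}


def daily_counts(log: EventLog, room: str | None = None,
                 sensor_kind: str | None = None, channel: str | None = None,
                 gaps: list[GapInterval] | None = None) -> DailyCountSeries:
    """Count matching firings per local day over the observation span.

    Days fully inside an absence gap (if ``gaps`` given) are dropped from the
    series: the home was empty, so a zero there is not a behavioral zero.
    Partial-day absences keep the day with its observed count.
    """
    days = log.span_days
    if not days:
        return DailyCountSeries(pd.Series(dtype=float), room, sensor_kind, channel)
    matched = log.filter(room, sensor_kind, channel)
    per_day = matched["timestamp"].dt.date.value_counts()
    series = pd.Series([float(per_day.get(d, 0)) for d in days], index=days)
    if gaps:
        drop = absent_days(gaps, days)
        series = series[[d for d in days if d not in drop]]
    return DailyCountSeries(series, room, sensor_kind, channel)


def replace_high_outliers(series: DailyCountSeries,
                          cfg: CleaningConfig | None = None) -> DailyCountSeries:
    """Mean-replace values above the Q3 + k*IQR fence.

    Quartiles use linear interpolation of order statistics (numpy default).
    The replacement mean is taken over the non-outlier values only; values at
    or below the fence are untouched.  Series with fewer than 4 values are
    returned unchanged with a warning.
    """
    cfg = cfg or CleaningConfig()
    vals = series.series.to_numpy(dtype=float)
    if len(vals) < 4:
        warnings.warn("fewer than 4 values; outlier repair skipped", stacklevel=2)
        return series
    q1, q3 = np.percentile(vals, [25, 75])
    fence = q3 + cfg.outlier_multiplier * (q3 - q1)
    high = vals > fence
    if not high.any():
        return series
    repaired = vals.copy()
    repaired[high] = vals[~high].mean()
    return DailyCountSeries(pd.Series(repaired, index=series.series.index),
                            series.room, series.sensor_kind, series.channel)


def gaps_to_frame(gaps: list[GapInterval]) -> pd.DataFrame:
    """Gap report as a writable table (start, end, scope, label, sensor)."""
    return pd.DataFrame(
        [
            {
                "start": g.start, "end": g.end, "scope": g.scope,
                "label": g.label,
                "sensor": "" if g.sensor is None else "/".join(g.sensor),
            }
            for g in gaps
        ],
        columns=["start", "end", "scope", "label", "sensor"],
    )
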