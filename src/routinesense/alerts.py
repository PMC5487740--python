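"""Two-level alert engine: missed routines, excessive stays, deviations.

Alert design principles, all aimed at keeping false positives tolerable:

* **Two-sensor corroboration** — a missed appliance routine (no kettle
  firing near the expected median) alerts only if the corroborating motion
  sensor in the same room is *also* silent in the window.  Motion presence
  vetoes the alert: the resident was up and about, so the likeliest story is
  a skipped cup of tea or a dead appliance sensor, not an emergency.
* **Maximum length of stay** — rooms with a specific purpose (bathroom,
  kitchen) should not hold a resident for hours.  A stay is the interval
  from the first firing in a room following activity elsewhere to the next
  firing outside it; overlong stays alert unless the silence elsewhere is a
  classified whole-home absence.
* **Suppression** — no alert of any kind is emitted for a day classified
  absent: an empty house is quiet for the right reasons.
* **Evidence** — every alert carries a routine-versus-actual summary and the
  day's timeline, so a carer can judge it at a glance.

The engine is batch and pure: identical (log, config, history) inputs yield
an identical, chronologically ordered feed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date, time, timedelta

import pandas as pd

from .change_detection import (THETA_HIGH, THETA_LOW, deviation,
                               weekday_baseline)
from .cleaning import GapInterval, absent_days
from .exceptions import ColdStartError
from .routines import RoutineWindow
from .sensor_io import EventLog

logger = logging.getLogger(__name__)

MORNING_END = time(12, 0)


@dataclass(frozen=True)
class AlertConfig:
    """Per-resident alerting configuration.

    routines : (RoutineWindow, expected median time, corroborating motion
        room) triples; the median comes from history, not the day under test.
    max_stay : per-room maximum stay durations.
    theta_low/theta_high : deviation-score thresholds (alert sensitivity).
    deviation_target : (room, kind, channel) profiled against the weekday
        baseline; window_weeks sets the moving-window length.
    """

    routines: tuple = ()  # of (RoutineWindow, time, str)
    max_stay: dict = field(default_factory=dict)  # room -> timedelta
    theta_low: float = THETA_LOW
    theta_high: float = THETA_HIGH
    deviation_target: tuple = (None, "motion", None)  # whole-home motion
    window_weeks: int = 6

    def __post_init__(self):
        for room, stay in self.max_stay.items():
            if stay <= timedelta(0):
                raise ValueError("max_stay must be positive")
        for w, med, corroborating in self.routines:
            if w.sensor_kind == "motion" and corroborating == w.room:
                raise ValueError(
                    "corroborating sensor must differ from the primary target")


@dataclass(frozen=True)
class Alert:
    """One emitted alert with its evidence and the day's event timeline."""

    day: date
    at: pd.Timestamp
    kind: str  # routine_missed | max_stay_exceeded | deviation
    level: str  # low | high
    evidence: dict  # routine-vs-actual summary
    timeline: tuple  # the day's event times (HH:MM:SS room/kind strings)

    def __post_init__(self):
        if not self.evidence:
            raise ValueError("every alert must carry evidence")

    def to_json(self) -> str:
        return json.dumps({
            "day": self.day.isoformat(), "at": str(self.at), "kind": self.kind,
            "level": self.level, "evidence": self.evidence,
            "timeline": list(self.timeline),
        }, default=str)


def _day_timeline(log: EventLog, day: date) -> tuple:
    ev = log.events
    sel = ev[ev["timestamp"].dt.date == day]
    return tuple(
        f"{ts.strftime('%H:%M:%S')} {room}/{kind}" + (f"/{ch}" if ch else "")
        for ts, room, kind, ch in zip(sel["timestamp"], sel["room"],
                                      sel["sensor_kind"], sel["channel"])
    )


def _window_count(log: EventLog, day: date, start: time, end: time,
                  room=None, sensor_kind=None, channel=None) -> int:
    ev = log.filter(room, sensor_kind, channel)
    lo = pd.Timestamp(day) + pd.Timedelta(hours=start.hour, minutes=start.minute,
                                          seconds=start.second)
    hi = pd.Timestamp(day) + pd.Timedelta(hours=end.hour, minutes=end.minute,
                                          seconds=end.second)
    return int(((ev["timestamp"] >= lo) & (ev["timestamp"] <= hi)).sum())


def routine_missed_alert(day: date, log: EventLog, w: RoutineWindow,
                         expected_median: time, corroborating_room: str,
                         gaps: list[GapInterval] = ()) -> Alert | None:
    """Missed-routine check with the two-sensor veto.

    Fires iff the day is observable, the primary channel shows no firing
    within expected_median +/- tolerance, AND the corroborating motion sensor
    is also silent in the window.  Level is high when the corroborating room
    shows no motion all morning (resident possibly down), low otherwise.
    """
    if day in absent_days(list(gaps), [day]):
        return None
    for g in gaps:
        if g.label == "battery_failure" and g.sensor == w.target and g.covers_day(day):
            return None
    med = timedelta(hours=expected_median.hour, minutes=expected_median.minute,
                    seconds=expected_median.second)
    lo_td = max(med - w.tolerance, timedelta(0))
    hi_td = min(med + w.tolerance, timedelta(hours=23, minutes=59, seconds=59))
    lo = (pd.Timestamp(day) + lo_td).time()
    hi = (pd.Timestamp(day) + hi_td).time()
    primary = _window_count(log, day, lo, hi, w.room, w.sensor_kind, w.channel)
    if primary > 0:
        return None
    corro = _window_count(log, day, w.start, w.end, corroborating_room, "motion", "")
    if corro > 0:
        logger.info("%s: %s missed but %s motion present - vetoed "
                    "(possible appliance sensor issue)", day, w.label,
                    corroborating_room)
        return None
    morning = _window_count(log, day, time(0, 0), MORNING_END,
                            corroborating_room, "motion", "")
    level = "high" if morning == 0 else "low"
    return Alert(
        day=day, at=pd.Timestamp(day) + hi_td, kind="routine_missed",
        level=level,
        evidence={
            "routine": w.label,
            "expected": f"{lo.strftime('%H:%M')}-{hi.strftime('%H:%M')} "
                        f"(median {expected_median.strftime('%H:%M')} "
                        f"± {int(w.tolerance.total_seconds() // 60)} min)",
            "observed_primary_firings": primary,
            "corroborating_motion_in_window": corro,
            "corroborating_motion_all_morning": morning,
        },
        timeline=_day_timeline(log, day),
    )


def max_stay_alert(log: EventLog, room: str, max_stay: timedelta,
                   gaps: list[GapInterval] = ()) -> list[Alert]:
    """Alerts for stays in ``room`` exceeding ``max_stay``.

    A stay runs from the first firing in the room following activity
    elsewhere to the next firing outside the room.  Intervals overlapping a
    classified whole-home absence are not stays (nobody is in the room).
    Unterminated stays at the end of the log are not scored: without a
    subsequent transition they are indistinguishable from departure.
    """
    motion = log.filter(sensor_kind="motion")
    absences = [g for g in gaps if g.label == "absence"]
    alerts = []
    stay_start = None
    prev_room = None
    for ts, rm in zip(motion["timestamp"], motion["room"]):
        if rm == room:
            if stay_start is None and prev_room != room:
                stay_start = ts
        else:
            if stay_start is not None:
                duration = ts - stay_start
                overlaps_absence = any(g.start < ts and stay_start < g.end
                                       for g in absences)
                if duration > max_stay and not overlaps_absence:
                    day = stay_start.date()
                    alerts.append(Alert(
                        day=day, at=ts, kind="max_stay_exceeded", level="high",
                        evidence={
                            "room": room,
                            "stay_start": str(stay_start),
                            "stay_end": str(ts),
                            "duration_min": round(duration.total_seconds() / 60, 1),
                            "max_stay_min": round(max_stay.total_seconds() / 60, 1),
                        },
                        timeline=_day_timeline(log, day),
                    ))
                stay_start = None
        prev_room = rm
    return alerts


def run_alert_engine(log: EventLog, cfg: AlertConfig,
                     gaps: list[GapInterval] = (),
                     exclude_baseline_days: set = frozenset()) -> list[Alert]:
    """Evaluate all alert kinds day by day; deterministic chronological feed.

    Component failures (cold-start baselines, empty days) are logged and
    skipped, never aborting the whole feed.  Days classified absent are
    fully suppressed.
    """
    feed: list[Alert] = []
    days = log.span_days
    suppressed = absent_days(list(gaps), days)

    for w, med, corroborating in cfg.routines:
        for d in days:
            if d in suppressed:
                continue
            a = routine_missed_alert(d, log, w, med, corroborating, gaps)
            if a is not None:
                feed.append(a)

    for room, stay in sorted(cfg.max_stay.items()):
        feed.extend(a for a in max_stay_alert(log, room, stay, gaps)
                    if a.day not in suppressed)

    room, kind, channel = cfg.deviation_target
    for d in days:
        if d in suppressed:
            continue
        try:
            base = weekday_baseline(log, d, room, kind, channel,
                                    cfg.window_weeks,
                                    exclude_days=set(exclude_baseline_days)
                                    | suppressed)
        except ColdStartError:
            continue
        from .profiles import daily_bin_vector
        rep = deviation(daily_bin_vector(log, d, room, kind, channel), base,
                        day=d, theta_low=cfg.theta_low,
                        theta_high=cfg.theta_high)
        if rep.level != "none":
            feed.append(Alert(
                day=d, at=pd.Timestamp(d) + pd.Timedelta(days=1), kind="deviation",
                level=rep.level,
                evidence={
                    "score": round(rep.score, 3),
                    "baseline_days": [x.isoformat() for x in base.contributing_days],
                    "worst_bins": sorted(
                        range(24), key=lambda h: -abs(rep.per_bin[h]))[:3],
                },
                timeline=_day_timeline(log, d),
            ))

    feed.sort(key=lambda a: (a.at, a.kind, a.level))
    return feed


def feed_to_jsonl(feed: list[Alert]) -> str:
    return "\n".join(a.to_json() for a in feed) + ("\n" if feed else "")


def feed_to_text(feed: list[Alert]) -> str:
    """Human-readable report of an alert feed."""
    if not feed:
        return "No alerts.\n"
    lines = []
    for a in feed:
        lines.append(f"[{a.level.upper():>4}] {a.day} {a.kind}")
        for k, v in a.evidence.items():
            lines.append(f"    {k}: {v}")
    return "\n".join(lines) + "\n"
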