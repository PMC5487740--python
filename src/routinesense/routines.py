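"""Routine quantification: timing dispersion, day partition, adherence.

For monitoring, a routine (say breakfast) is useful as an alert trigger only
if it is (a) consistent in timing and (b) a regular daily occurrence.  Both
are measured on a per-resident *routine window* — e.g. all kettle use
between 05:00 and 09:00:

* **Timing** — median / quartiles / SD of the pooled firing times.
* **Day partition** — each observed day is *absent* (whole home empty),
  *unobserved* (target sensor dead or not installed), *with_data* (the
  routine's sensor fired inside the window) or *not_taken* (present but the
  routine skipped).  The four labels tile the observation span exactly.
* **Adherence to schedule** — of the with-data days, the percentage on which
  the sensor fired within +/-30 minutes of the median time of use, the
  median being taken over the pooled firings of all days.

A short routinization-preference questionnaire (8 true/false items, scored
as percent "prefers routine" answers) contextualizes the sensor statistic:
low adherence means something different for a resident who dislikes fixed
schedules.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, time, timedelta
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .cleaning import GapInterval
from .exceptions import UndefinedStatisticError
from .sensor_io import EventLog


def _round_half_away(x: Decimal, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(x.quantize(q, rounding=ROUND_HALF_UP))


def _minutes(t: time) -> float:
    return t.hour * 60 + t.minute + t.second / 60


def _to_time(minutes: float) -> time:
    total = int(round(minutes * 60)) % 86400
    return time(total // 3600, (total % 3600) // 60, total % 60)


@dataclass(frozen=True)
class RoutineWindow:
    """A named clock window and target sensor defining one routine."""

    label: str = "breakfast"
    start: time = time(5, 0)
    end: time = time(9, 0)
    room: str = "kitchen"
    sensor_kind: str = "power"
    channel: str | None = "kettle"
    tolerance: timedelta = timedelta(minutes=30)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must precede end")
        if self.tolerance <= timedelta(0):
            raise ValueError("tolerance must be positive")

    @property
    def target(self) -> tuple:
        return (self.room, self.sensor_kind, self.channel)


@dataclass(frozen=True)
class TimingSummary:
    """Location and dispersion of pooled firing times."""

    median_time: time
    q1: time
    q3: time
    iqr: timedelta
    sd: timedelta
    n: int


@dataclass(frozen=True)
class DayPartition:
    """Per-day labels over the observation span plus the label totals."""

    labels: dict  # date -> absent | with_data | not_taken | unobserved
    absent: int
    with_data: int
    not_taken: int
    unobserved: int

    @property
    def span(self) -> int:
        return self.absent + self.with_data + self.not_taken + self.unobserved

    @property
    def total_days_with_data(self) -> int:
        """Days the target sensor was observable (span minus unobserved)."""
        return self.span - self.unobserved


@dataclass(frozen=True)
class AdherenceResult:
    """The headline statistic: partition + adherence to the median schedule."""

    partition: DayPartition
    median_time: time
    adherent_days: int
    adherence_pct: float
    report: str = "one-decimal"


@dataclass(frozen=True)
class RoutinizationAnswers:
    """Responses to the 8-item preference-for-routinization scale."""

    items: tuple  # 8 booleans, True = preferred-routine response

    def __post_init__(self):
        if len(self.items) != 8:
            raise ValueError("the shortened scale has exactly 8 items")
        object.__setattr__(self, "items", tuple(bool(i) for i in self.items))


def window_firing_times(log: EventLog, w: RoutineWindow) -> dict:
    """Wall-clock firing times of the window's target, grouped by local day.

    Window bounds are closed at both ends.  Only days with at least one
    in-window target firing appear in the mapping.
    """
    ev = log.filter(w.room, w.sensor_kind, w.channel)
    out: dict[date, list[time]] = {}
    for ts in ev["timestamp"]:
        t = ts.time()
        if w.start <= t <= w.end:
            out.setdefault(ts.date(), []).append(t)
    return out


def timing_summary(times) -> TimingSummary:
    """Median/quartiles (linear-interpolated order statistics) and population
    SD of pooled wall-clock times, computed on minutes-since-midnight."""
    times = list(times)
    if not times:
        raise UndefinedStatisticError("timing summary needs at least one time")
    mins = np.array([_minutes(t) for t in times], dtype=float)
    q1, med, q3 = np.percentile(mins, [25, 50, 75])
    sd = float(mins.std(ddof=0))
    return TimingSummary(
        median_time=_to_time(med), q1=_to_time(q1), q3=_to_time(q3),
        iqr=timedelta(minutes=float(q3 - q1)), sd=timedelta(minutes=sd),
        n=len(times),
    )


def partition_days(log: EventLog, w: RoutineWindow,
                   gaps: list[GapInterval] = ()) -> DayPartition:
    """Label every day of the span: absent / unobserved / with_data / not_taken.

    Precedence: a day fully inside an all-sensor absence gap is *absent*; else
    a day whose target sensor sits in a battery-failure gap (which includes
    "not installed until later") is *unobserved*; else *with_data* iff the
    target fired inside the window; else *not_taken*.
    """
    firings = window_firing_times(log, w)
    labels: dict[date, str] = {}
    absence = [g for g in gaps if g.label == "absence"]
    failure = [g for g in gaps
               if g.label == "battery_failure" and g.sensor == w.target]
    for d in log.span_days:
        if any(g.covers_day(d) for g in absence):
            labels[d] = "absent"
        elif any(g.covers_day(d) for g in failure):
            labels[d] = "unobserved"
        elif d in firings:
            labels[d] = "with_data"
        else:
            labels[d] = "not_taken"
    counts = {k: sum(1 for v in labels.values() if v == k)
              for k in ("absent", "with_data", "not_taken", "unobserved")}
    return DayPartition(labels, **counts)


def adherence_pct(adherent: int, with_data: int, report: str = "one-decimal") -> float:
    """100 * adherent / with_data, rounded half away from zero.

    ``report`` selects one-decimal (Table-style, e.g. 98.3) or integer
    (text-style, e.g. 63) output.
    """
    if with_data < 1:
        raise UndefinedStatisticError("adherence undefined with zero with-data days")
    if not 0 <= adherent <= with_data:
        raise ValueError("adherent days must lie in [0, with_data]")
    frac = Decimal(100 * adherent) / Decimal(with_data)
    if report == "one-decimal":
        return _round_half_away(frac, 1)
    return int(_round_half_away(frac, 0))


def adherence(log: EventLog, w: RoutineWindow, gaps: list[GapInterval] = (),
              report: str = "one-decimal") -> AdherenceResult:
    """Adherence to schedule: share of with-data days firing near the median.

    The median time of use is computed over ALL pooled in-window firings
    across days; a with-data day is adherent iff at least one target firing
    falls within the closed interval [median - tolerance, median + tolerance].
    """
    partition = partition_days(log, w, gaps)
    firings = window_firing_times(log, w)
    pooled = [t for d, ts in firings.items()
              if partition.labels.get(d) == "with_data" for t in ts]
    if not pooled:
        raise UndefinedStatisticError("adherence undefined with zero with-data days")
    med = float(np.percentile([_minutes(t) for t in pooled], 50))
    tol = timedelta.total_seconds(w.tolerance) / 60
    adherent = sum(
        1
        for d, ts in firings.items()
        if partition.labels.get(d) == "with_data"
        and any(med - tol <= _minutes(t) <= med + tol for t in ts)
    )
    pct = adherence_pct(adherent, partition.with_data, report)
    return AdherenceResult(partition, _to_time(med), adherent, pct, report)


def routinization_score(answers: RoutinizationAnswers) -> int:
    """Percentage of preferred-routine responses, rounded half away from zero."""
    positives = sum(answers.items)
    return int(_round_half_away(Decimal(100 * positives) / Decimal(8), 0))


def adherence_table_row(label: str, result: AdherenceResult) -> dict:
    """One routine as a row of the adherence summary table."""
    p = result.partition
    return {
        "routine": label,
        "days_absent": p.absent,
        "days_with_data": p.with_data,
        "days_not_taken": p.not_taken,
        "total_days_with_data": p.total_days_with_data,
        "median_time": result.median_time.strftime("%H:%M"),
        "adherent_days": result.adherent_days,
        "adherence_pct": result.adherence_pct,
    }
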