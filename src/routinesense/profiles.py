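"""24-hour cyclical (radar) profiles and reverse-scale absence views.

A routine is a wall-clock phenomenon, so its natural summary is cumulative
firing frequency around the 24-hour circle.  Events are grouped by hour
+/- 30 minutes: bin ``h`` collects times in ``[h:00 - 30 min, h:00 + 30 min)``,
with 23:30-23:59 wrapping into bin 0.  Stacked over many days, sharp spikes
mark strict time schedules and flat arcs mark diffuse behavior.

The *absence view* reverses the radial scale (``scale_max - count``) so that
hours with **no** movement sit at the outer edge — the right visual emphasis
when the question is "when is this person regularly out of the house?".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, time

import numpy as np

from .sensor_io import EventLog

_WEEKDAYS = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


def hour_bin(t: time) -> int:
    """Map a wall-clock time to its hour-centered bin (0-23).

    Bin ``h`` spans ``[h:00 - 30 min, h:00 + 30 min)``; the half-hour before
    midnight wraps into bin 0.
    """
    seconds = t.hour * 3600 + t.minute * 60 + t.second
    return int((seconds + 1800) // 3600) % 24


@dataclass(frozen=True)
class DayFilter:
    """A day predicate with a human-readable description.

    Built from a mini-language: ``"all"``, weekday names/ranges
    (``"Sun"``, ``"Mon-Sat"``, ``"Mon,Thu,Sat"``), month windows
    (``"month 1-2"``), or ISO date ranges (``"2014-01-01..2014-03-01"``).
    """

    description: str
    _predicate: object

    def __call__(self, d: date) -> bool:
        return self._predicate(d)

    @classmethod
    def parse(cls, expr: str) -> "DayFilter":
        expr = expr.strip()
        low = expr.lower()
        if low in ("all", "", "*"):
            return cls("all days", lambda d: True)
        m = re.fullmatch(r"month\s+(\d+)(?:-(\d+))?", low)
        if m:
            lo = int(m.group(1))
            hi = int(m.group(2) or lo)
            if not (1 <= lo <= hi <= 12):
                raise ValueError(f"bad month window {expr!r}")
            return cls(expr, lambda d, lo=lo, hi=hi: lo <= d.month <= hi)
        m = re.fullmatch(r"(\d{4}-\d{2}-\d{2})\.\.(\d{4}-\d{2}-\d{2})", expr)
        if m:
            lo, hi = date.fromisoformat(m.group(1)), date.fromisoformat(m.group(2))
            return cls(expr, lambda d, lo=lo, hi=hi: lo <= d <= hi)
        # weekday sets: names and dashed ranges, comma separated
        days: set[int] = set()
        for part in expr.split(","):
            part = part.strip().title()
            if "-" in part:
                a, b = (p.strip() for p in part.split("-", 1))
                ia, ib = _WEEKDAYS.index(a), _WEEKDAYS.index(b)
                idx = range(ia, ib + 1) if ia <= ib else \
                    list(range(ia, 7)) + list(range(0, ib + 1))
                days.update(idx)
            else:
                days.add(_WEEKDAYS.index(part))
        return cls(expr, lambda d, days=frozenset(days): d.weekday() in days)

    @classmethod
    def single_day(cls, d: date) -> "DayFilter":
        return cls(d.isoformat(), lambda x, d=d: x == d)

    @classmethod
    def in_set(cls, days, description="day set") -> "DayFilter":
        s = frozenset(days)
        return cls(description, lambda d, s=s: d in s)


@dataclass(frozen=True)
class CyclicalProfile:
    """Cumulative hourly-binned firing counts over a subset of days."""

    bins: np.ndarray  # 24 non-negative counts
    subset: str
    room: str | None
    sensor_kind: str | None
    channel: str | None
    n_days: int

    def __post_init__(self):
        bins = np.asarray(self.bins, dtype=float)
        if bins.shape != (24,):
            raise ValueError("a cyclical profile has exactly 24 bins")
        if (bins < 0).any():
            raise ValueError("bin counts must be >= 0")
        object.__setattr__(self, "bins", bins)

    @property
    def total(self) -> float:
        return float(self.bins.sum())

    def normalized(self) -> np.ndarray:
        """Per-day mean counts (raw bins / n_days); zeros if no days."""
        if self.n_days == 0:
            return np.zeros(24)
        return self.bins / self.n_days


@dataclass(frozen=True)
class AbsenceProfile:
    """Reverse-scale view: zero movement maps to the outer edge."""

    bins: np.ndarray  # scale_max - count, per bin
    scale_max: float
    subset: str = ""
    degenerate: bool = False  # True when the source profile was all zero

    def counts(self) -> np.ndarray:
        """Invert back to the source counts."""
        return self.scale_max - self.bins


def cyclical_profile(log: EventLog, room: str | None = None,
                     sensor_kind: str | None = None, channel: str | None = None,
                     day_filter: DayFilter | str = "all") -> CyclicalProfile:
    """Build the 24-bin cumulative profile of matching events.

    ``day_filter`` restricts which local days contribute; ``n_days`` records
    how many days of the observation span passed the filter (even if they
    contributed no events).
    """
    if isinstance(day_filter, str):
        day_filter = DayFilter.parse(day_filter)
    days = [d for d in log.span_days if day_filter(d)]
    day_set = set(days)
    ev = log.filter(room, sensor_kind, channel)
    ts = ev["timestamp"]
    if len(ts):
        mask = ts.dt.date.isin(day_set).to_numpy()
        secs = (ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second).to_numpy()
        idx = ((secs[mask] + 1800) // 3600) % 24
        bins = np.bincount(idx, minlength=24).astype(float)
    else:
        bins = np.zeros(24)
    return CyclicalProfile(bins, day_filter.description, room, sensor_kind,
                           channel, len(days))


def absence_view(profile: CyclicalProfile) -> AbsenceProfile:
    """Reverse the radial scale: transformed value = scale_max - count."""
    scale_max = float(profile.bins.max())
    return AbsenceProfile(scale_max - profile.bins, scale_max,
                          subset=profile.subset, degenerate=scale_max == 0.0)


def render_radar(profile, path, title: str | None = None, color="tab:blue",
                 fill_alpha=0.25) -> None:
    """Render a profile (or absence view) as a 24-spoke polar plot.

    00:00 sits at the top and hours run clockwise, matching a 24-hour clock
    face.  Output format follows the path suffix (png/svg).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "routinesense"  # deterministic svg ids
    bins = np.asarray(profile.bins, dtype=float)
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    r = np.append(bins, bins[0])
    th = np.append(theta, theta[0])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.plot(th, r, color=color, lw=1.5)
    ax.fill(th, r, color=color, alpha=fill_alpha)
    ax.set_xticks(theta)
    ax.set_xticklabels([f"{h:02d}" for h in range(24)], fontsize=7)
    if title:
        ax.set_title(title, fontsize=10)
    fig.savefig(path, dpi=150, bbox_inches="tight",
                metadata={"Software": None} if str(path).endswith(".png") else
                {"Date": None})
    plt.close(fig)


def profile_to_rows(profile: CyclicalProfile) -> list[dict]:
    """CSV/JSON-ready rows (bin_hour, count)."""
    return [{"bin_hour": h, "count": float(profile.bins[h])} for h in range(24)]


def daily_bin_vector(log: EventLog, day: date, room=None, sensor_kind=None,
                     channel=None) -> np.ndarray:
    """The 24-bin count vector of a single local day."""
    return cyclical_profile(log, room, sensor_kind, channel,
                            DayFilter.single_day(day)).bins
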