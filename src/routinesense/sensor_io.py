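"""Reading, validation, timezone localization and writing of sensor event logs.

The pipeline's universal currency is the :class:`EventLog`: a time-sorted
table of atomic sensor events — passive-infrared motion firings and 5-minute
appliance power samples — for a single residence.

The CSV dialect is fixed: UTF-8, comma separated, header
``timestamp,residence_id,room,sensor_kind,channel,value``.  Timestamps are
ISO-8601 at second resolution; UTC files carry an explicit ``Z`` designator,
localized files carry none, so a file's localization state is machine
checkable.  Wall-clock localization is driven by an explicit
:class:`TimezoneSchedule` (ordered UTC-offset segments) rather than a tz
database: monitored deployments publish their offsets (e.g. standard vs
daylight time) explicitly, and an auditable offset table is preferable to
hidden zoneinfo lookups.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exceptions import ConfigError, CoverageError, FormatError, RowError

ROOMS = frozenset({"lounge", "kitchen", "bedroom", "bathroom", "other"})
SENSOR_KINDS = frozenset({"motion", "power"})

#: canonical column order of the event CSV
COLUMNS = ["timestamp", "residence_id", "room", "sensor_kind", "channel", "value"]


@dataclass(frozen=True)
class SensorEvent:
    """One sensor firing (motion) or one 5-minute power sample (power)."""

    timestamp: pd.Timestamp
    residence_id: str
    room: str
    sensor_kind: str
    channel: str  # appliance name for power, "" for motion
    value: float  # kWh for power samples, 1.0 for motion firings

    def __post_init__(self):
        if self.room not in ROOMS:
            raise ValueError(f"unknown room {self.room!r}")
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(f"unknown sensor kind {self.sensor_kind!r}")
        if self.sensor_kind == "motion" and (self.channel or self.value != 1.0):
            raise ValueError("motion events must have value 1 and empty channel")
        if self.sensor_kind == "power" and (not self.channel or self.value < 0):
            raise ValueError("power events need a channel and value >= 0")


@dataclass
class EventLog:
    """Time-sorted sensor events of one residence plus span metadata.

    ``events`` is a DataFrame with columns :data:`COLUMNS`; ``localized``
    records whether timestamps are UTC (False) or local wall-clock (True).
    ``first_day``/``last_day`` declare the observation span (local days once
    localized); they default to the days of the first and last event.
    """

    events: pd.DataFrame
    residence_id: str = ""
    first_day: date | None = None
    last_day: date | None = None
    localized: bool = False
    parse_errors: list = field(default_factory=list)

    def __post_init__(self):
        ev = self.events
        missing = [c for c in COLUMNS if c not in ev.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        ev = ev[COLUMNS].reset_index(drop=True)
        if not isinstance(ev["timestamp"].dtype, np.dtype) or \
                ev["timestamp"].dtype.kind != "M":
            ev["timestamp"] = pd.to_datetime(ev["timestamp"])
        ev["value"] = ev["value"].astype(float)
        if not ev["timestamp"].is_monotonic_increasing:
            ev = ev.sort_values("timestamp", kind="stable").reset_index(drop=True)
        self.events = ev
        if len(ev):
            if not self.residence_id:
                self.residence_id = str(ev["residence_id"].iloc[0])
            if not (ev["residence_id"] == self.residence_id).all():
                raise FormatError("all events must share one residence_id")
            if self.first_day is None:
                self.first_day = ev["timestamp"].iloc[0].date()
            if self.last_day is None:
                self.last_day = ev["timestamp"].iloc[-1].date()

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        if len(self) == 0 and len(other) == 0:
            # residence id is not recoverable from a header-only file
            return self.localized == other.localized
        return (
            self.residence_id == other.residence_id
            and self.localized == other.localized
            and len(self) == len(other)
            and (len(self) == 0 or self.events.reset_index(drop=True).equals(
                other.events.reset_index(drop=True)))
        )

    @property
    def span_days(self) -> list[date]:
        """Every day of the declared observation span, inclusive."""
        if self.first_day is None:
            return []
        n = (self.last_day - self.first_day).days + 1
        return [self.first_day + timedelta(days=d) for d in range(n)]

    def filter(self, room=None, sensor_kind=None, channel=None) -> pd.DataFrame:
        """Rows matching the given provenance coordinates (None = any)."""
        ev = self.events
        mask = pd.Series(True, index=ev.index)
        if room is not None:
            mask &= ev["room"] == room
        if sensor_kind is not None:
            mask &= ev["sensor_kind"] == sensor_kind
        if channel is not None:
            mask &= ev["channel"] == channel
        return ev[mask]

    def sensors(self) -> list[tuple[str, str, str]]:
        """Distinct (room, sensor_kind, channel) triples present in the log."""
        if not len(self.events):
            return []
        uniq = self.events[["room", "sensor_kind", "channel"]].drop_duplicates()
        return sorted(map(tuple, uniq.itertuples(index=False)))


@dataclass(frozen=True)
class TimezoneSchedule:
    """Ordered (start instant UTC, offset minutes) segments.

    Each segment applies from its start (inclusive) until the next segment's
    start (exclusive): events exactly on a boundary belong to the later
    segment.
    """

    segments: tuple  # of (pd.Timestamp, int)

    def __post_init__(self):
        segs = tuple((pd.Timestamp(s), int(o)) for s, o in self.segments)
        starts = [s for s, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigError("segment starts must be strictly increasing")
        if any(abs(o) > 14 * 60 for _, o in segs):
            raise ConfigError("offsets must lie within +/-14 hours")
        object.__setattr__(self, "segments", segs)

    def offset_at(self, t: pd.Timestamp) -> int:
        """UTC offset (minutes) in force at UTC instant ``t``."""
        off = None
        for start, o in self.segments:
            if t >= start:
                off = o
            else:
                break
        if off is None:
            raise CoverageError(f"instant {t} precedes the first segment")
        return off

    @classmethod
    def constant(cls, offset_minutes: int, start="1970-01-01") -> "TimezoneSchedule":
        return cls(((pd.Timestamp(start), offset_minutes),))

    @classmethod
    def from_config(cls, entries) -> "TimezoneSchedule":
        """Build from config entries: list of {start, offset_minutes}."""
        return cls(tuple((e["start"], e["offset_minutes"]) for e in entries))


def _validate_row(i: int, row) -> None:
    room, kind, channel, value = row
    if room not in ROOMS:
        raise RowError(i, f"unknown room {room!r}")
    if kind not in SENSOR_KINDS:
        raise RowError(i, f"unknown sensor_kind {kind!r}")
    if kind == "motion":
        if channel:
            raise RowError(i, "motion events must have empty channel")
        if value != 1.0:
            raise RowError(i, "motion events must have value 1")
    else:
        if not channel:
            raise RowError(i, "power events need a channel")
        if value < 0:
            raise RowError(i, "power value must be >= 0")


def read_event_log(source, dialect: dict | None = None, fail_fast: bool = False) -> EventLog:
    """Parse an event CSV into a sorted :class:`EventLog`.

    Parameters
    ----------
    source : path, file object or text
        CSV input with a header row.
    dialect : optional mapping of canonical column name -> actual column name.
    fail_fast : raise on the first bad row instead of collecting it.

    Rows violating the event schema (bad room/kind, inconsistent
    channel/value, unparseable timestamp) are rejected; their row numbers and
    messages are collected on ``log.parse_errors`` unless ``fail_fast``.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    colmap = dict(dialect or {})
    rename = {colmap.get(c, c): c for c in COLUMNS}
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    raw = raw[COLUMNS]

    # a file with no zone designator anywhere is a localized (wall-clock) file
    has_zone = raw["timestamp"].str.contains(r"(?:Z|[+-]\d{2}:?\d{2})$", na=False)
    localized = bool(len(raw)) and not has_zone.any()
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601",
                        utc=not localized)
    if not localized and isinstance(ts.dtype, pd.DatetimeTZDtype):
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    def _exact_float(x):  # python float(): correctly-rounded, repr round-trips
        try:
            return float(x)
        except ValueError:
            return np.nan

    value = raw["value"].map(_exact_float)

    errors: list[RowError] = []
    keep = []
    for i in range(len(raw)):
        rowno = i + 2  # header is line 1
        try:
            if pd.isna(ts.iloc[i]):
                raise RowError(rowno, f"unparseable timestamp {raw['timestamp'].iloc[i]!r}")
            if pd.isna(value.iloc[i]):
                raise RowError(rowno, f"unparseable value {raw['value'].iloc[i]!r}")
            _validate_row(
                rowno,
                (raw["room"].iloc[i], raw["sensor_kind"].iloc[i],
                 raw["channel"].iloc[i], float(value.iloc[i])),
            )
            keep.append(i)
        except RowError as e:
            if fail_fast:
                raise
            errors.append(e)

    ev = pd.DataFrame(
        {
            "timestamp": ts.iloc[keep].reset_index(drop=True)
            if keep else pd.Series([], dtype="datetime64[ns]"),
            "residence_id": raw["residence_id"].iloc[keep].reset_index(drop=True),
            "room": raw["room"].iloc[keep].reset_index(drop=True),
            "sensor_kind": raw["sensor_kind"].iloc[keep].reset_index(drop=True),
            "channel": raw["channel"].iloc[keep].reset_index(drop=True),
            "value": value.iloc[keep].astype(float).reset_index(drop=True),
        }
    )
    return EventLog(ev, localized=localized if len(ev) else localized,
                    parse_errors=errors)


def localize(log: EventLog, tz: TimezoneSchedule) -> EventLog:
    """Shift UTC timestamps to local wall-clock per the offset schedule.

    Event order is preserved by construction (events keep their positions),
    even where a backward offset change makes wall-clock times repeat.
    """
    if log.localized:
        raise ConfigError("log is already localized")
    if not len(log):
        return replace(log, localized=True, first_day=None, last_day=None)
    ts = log.events["timestamp"]
    starts = pd.Series([s for s, _ in tz.segments])
    offsets = pd.Series([o for _, o in tz.segments])
    idx = starts.searchsorted(ts, side="right") - 1
    if (idx < 0).any():
        bad = ts[idx < 0].iloc[0]
        raise CoverageError(f"event at {bad} precedes timezone coverage")
    shifted = ts + pd.to_timedelta(offsets.iloc[idx].to_numpy(), unit="m")
    ev = log.events.copy()
    ev["timestamp"] = shifted.to_numpy()
    return EventLog(ev, residence_id=log.residence_id, localized=True)


def write_event_log(log: EventLog, sink) -> int:
    """Write the canonical event CSV; returns the byte count written.

    Canonical formatting: second-resolution ISO-8601 timestamps (``Z`` suffix
    for UTC logs, none for localized), ``repr`` float values (shortest exact
    round-trip), so write -> read -> write is bit-identical.
    """
    suffix = "" if log.localized else "Z"
    lines = [",".join(COLUMNS)]
    ev = log.events
    stamps = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    for i in range(len(ev)):
        lines.append(
            f"{stamps.iloc[i]}{suffix},{ev['residence_id'].iloc[i]},"
            f"{ev['room'].iloc[i]},{ev['sensor_kind'].iloc[i]},"
            f"{ev['channel'].iloc[i]},{float(ev['value'].iloc[i])!r}"
        )
    text = "\n".join(lines) + "\n"
    data = text.encode("utf-8")
    if hasattr(sink, "write"):
        try:
            sink.write(text)
        except TypeError:
            sink.write(data)
    else:
        with open(sink, "wb") as fh:
            fh.write(data)
    return len(data)
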