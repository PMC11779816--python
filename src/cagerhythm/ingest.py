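"""Reading, validating and writing home-cage activity data.

The on-disk dialects:

* Activity CSV (long, canonical): columns ``timestamp,animal_id,ali[,sex,genotype]``,
  ISO-8601 timestamps, one row per (animal, bin).  A wide dialect
  (``timestamp`` plus one column per animal) is accepted on read only.
* Schedule file: CSV ``start,end,state[,lux]`` or a JSON list of episode
  objects with the same keys.
* Metrics output: tidy CSV, one row per animal x phase (see
  :func:`write_metrics_table`).

Activity is the Animal Locomotion Index (ALI): the percentage of the cage
floor's capacitive electrodes activated within a time bin, in [0, 100].
Missing bins (welfare checks, cage removals) are first-class: they are held
as NaN in the value array and must never be conflated with zero activity.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "LIGHT",
    "DARK",
    "ValidationError",
    "ActivityTrace",
    "LightEpisode",
    "LightingSchedule",
    "ProtocolPhase",
    "read_activity_csv",
    "write_activity_csv",
    "read_schedule",
    "write_schedule",
    "write_metrics_table",
]

#: Sentinel used inside value arrays for missing bins.  Code must test with
#: ``np.isnan`` (or :attr:`ActivityTrace.missing_mask`), never with ``==``.
MISSING = np.nan

LIGHT = "LIGHT"
DARK = "DARK"

_SEXES = {"M", "F", "unknown"}


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates the data model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ActivityTrace:
    """One animal's uniformly binned ALI series.

    Parameters
    ----------
    animal_id
        Stable identifier of the animal / cage.
    start_time
        Wall-clock (timezone-naive) timestamp of the first bin's left edge.
    values
        Float array of ALI percentages in [0, 100]; NaN marks MISSING bins.
    bin_seconds
        Width of each bin; the platform default export is 60 s.
    sex, genotype
        Optional metadata carried through to output tables.
    """

    animal_id: str
    start_time: pd.Timestamp
    values: np.ndarray
    bin_seconds: int = 60
    sex: str = "unknown"
    genotype: str = "WT"

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is not None:
            self.start_time = self.start_time.tz_localize(None)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("trace values must be a non-empty 1-D array")
        if not isinstance(self.bin_seconds, (int, np.integer)) or self.bin_seconds <= 0:
            raise ValidationError(f"bin_seconds must be a positive integer, got {self.bin_seconds!r}")
        self.bin_seconds = int(self.bin_seconds)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            bad = finite[(finite < 0) | (finite > 100)][0]
            raise ValidationError(f"ALI value {bad} outside [0, 100] for animal {self.animal_id}")
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {sorted(_SEXES)}, got {self.sex!r}")

    # -- derived views ------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_hours(self) -> float:
        return self.bin_seconds / 3600.0

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_hours

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def times(self) -> pd.DatetimeIndex:
        """Left-edge timestamp of every bin."""
        return self.start_time + pd.to_timedelta(np.arange(self.n_bins) * self.bin_seconds, unit="s")

    def hours_since_start(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hours

    def with_values(self, values: np.ndarray, bin_seconds: int | None = None,
                    start_time: pd.Timestamp | None = None) -> "ActivityTrace":
        """Copy of this trace with replaced values (metadata preserved)."""
        return ActivityTrace(
            animal_id=self.animal_id,
            start_time=self.start_time if start_time is None else start_time,
            values=values,
            bin_seconds=self.bin_seconds if bin_seconds is None else bin_seconds,
            sex=self.sex,
            genotype=self.genotype,
        )

    def slice_hours(self, start_h: float, end_h: float) -> "ActivityTrace":
        """Sub-trace covering [start_h, end_h) hours since trace start."""
        i0 = int(round(start_h / self.bin_hours))
        i1 = int(round(end_h / self.bin_hours))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_bins)
        if i1 <= i0:
            raise ValidationError(f"empty slice [{start_h}, {end_h}) h for trace of {self.duration_hours} h")
        return self.with_values(
            self.values[i0:i1],
            start_time=self.start_time + pd.Timedelta(seconds=i0 * self.bin_seconds),
        )


@dataclass(frozen=True)
class LightEpisode:
    start: pd.Timestamp
    end: pd.Timestamp
    state: str  # LIGHT or DARK
    lux: float | None = None

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class LightingSchedule:
    """Ordered, non-overlapping light/dark episodes governing one cage."""

    episodes: list[LightEpisode]

    def __post_init__(self) -> None:
        eps = []
        for ep in self.episodes:
            start, end = pd.Timestamp(ep.start), pd.Timestamp(ep.end)
            state = str(ep.state).upper()
            if state not in (LIGHT, DARK):
                raise ValidationError(f"unknown lighting state {ep.state!r}")
            if end <= start:
                raise ValidationError(f"episode end {end} not after start {start}")
            eps.append(LightEpisode(start, end, state, ep.lux))
        eps.sort(key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise ValidationError(f"overlapping episodes at {b.start} (previous ends {a.end})")
        self.episodes = eps

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_cycle(cls, start: pd.Timestamp, n_days: int, lights_on_h: float = 7.0,
                   light_hours: float = 12.0, dark_hours: float = 12.0,
                   lux: float | None = 100.0) -> "LightingSchedule":
        """Expand a compact cycle spec (e.g. 12:12 LD, lights-on 07:00, D days).

        ``start`` is the date on which the first lights-on falls; episodes
        begin at that day's lights-on and alternate LIGHT/DARK for
        ``n_days`` cycles (2 x n_days episodes).
        """
        if n_days < 1:
            raise ValidationError("n_days must be >= 1")
        t = pd.Timestamp(start).normalize() + pd.Timedelta(hours=lights_on_h)
        eps: list[LightEpisode] = []
        for _ in range(int(n_days)):
            t_off = t + pd.Timedelta(hours=light_hours)
            t_next = t_off + pd.Timedelta(hours=dark_hours)
            eps.append(LightEpisode(t, t_off, LIGHT, lux))
            eps.append(LightEpisode(t_off, t_next, DARK, 0.0))
            t = t_next
        return cls(eps)

    @classmethod
    def constant(cls, start: pd.Timestamp, end: pd.Timestamp, state: str,
                 lux: float | None = None) -> "LightingSchedule":
        """Single-episode schedule: constant darkness (DD) or light (LL)."""
        return cls([LightEpisode(pd.Timestamp(start), pd.Timestamp(end), state, lux)])

    # -- queries ------------------------------------------------------------

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.episodes[0].start, self.episodes[-1].end

    def is_light(self, times: pd.DatetimeIndex | Sequence) -> np.ndarray:
        """Boolean array: is each timestamp inside a LIGHT episode?"""
        times = pd.DatetimeIndex(times)
        out = np.zeros(len(times), dtype=bool)
        for ep in self.episodes:
            if ep.state == LIGHT:
                out |= (times >= ep.start) & (times < ep.end)
        return out

    def light_onsets(self, min_duration_h: float = 6.0) -> list[pd.Timestamp]:
        """Starts of full-photoperiod LIGHT episodes (brief pulses excluded).

        A light pulse delivered in the night is a LIGHT episode too, but it
        does not redefine Zeitgeber time; episodes shorter than
        ``min_duration_h`` are therefore not treated as lights-on events.
        """
        return [ep.start for ep in self.episodes
                if ep.state == LIGHT and ep.duration_hours >= min_duration_h]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": [ep.start for ep in self.episodes],
                "end": [ep.end for ep in self.episodes],
                "state": [ep.state for ep in self.episodes],
                "lux": [ep.lux for ep in self.episodes],
            }
        )


@dataclass(frozen=True)
class ProtocolPhase:
    """A named, day-granular segment of the lighting protocol.

    ``start_day``/``end_day`` are half-open day indices relative to the
    trace start (day 0 = first 24 h of recording).
    """

    label: str
    start_day: int
    end_day: int

    LABELS = ("LD_BASELINE", "JETLAG_LD", "DD", "LD_REENTRAIN", "LP", "DD_POST_LP", "LL")

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ValidationError(f"unknown phase label {self.label!r}; expected one of {self.LABELS}")
        if self.end_day <= self.start_day:
            raise ValidationError(f"phase {self.label}: end_day must exceed start_day")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day


# ---------------------------------------------------------------------------
# Activity I/O
# ---------------------------------------------------------------------------

def _parse_timestamps(raw: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = parsed.index[parsed.isna()][0]
        raise ValidationError(f"malformed timestamp {raw.loc[bad]!r} at data row {bad + 1}")
    return parsed


def read_activity_csv(path: str | Path, bin_seconds: int | None = None,
                      column_map: dict[str, str] | None = None) -> list[ActivityTrace]:
    """Read an activity export into one :class:`ActivityTrace` per animal.

    Accepts the canonical long dialect (``timestamp,animal_id,ali``) and a
    wide dialect (``timestamp`` plus one ALI column per animal).  Rows are
    sorted by time; holes in the regular timestamp grid become MISSING bins.

    ``column_map`` renames columns of a non-standard export onto the
    canonical names, e.g. ``{"datetime": "timestamp", "cage": "animal_id"}``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "timestamp" not in df.columns:
        raise ValidationError(f"{path}: no 'timestamp' column (found {list(df.columns)})")

    if "animal_id" not in df.columns:
        # wide dialect: every non-timestamp column is one animal's ALI
        value_cols = [c for c in df.columns if c != "timestamp"]
        if not value_cols:
            raise ValidationError(f"{path}: wide dialect needs at least one animal column")
        df = df.melt(id_vars=["timestamp"], value_vars=value_cols,
                     var_name="animal_id", value_name="ali")
        df = df.dropna(subset=["ali"])
    if "ali" not in df.columns:
        raise ValidationError(f"{path}: no 'ali' column")

    df["timestamp"] = _parse_timestamps(df["timestamp"])
    df["ali"] = pd.to_numeric(df["ali"], errors="coerce")
    finite = df["ali"].dropna()
    out_of_range = finite[(finite < 0) | (finite > 100)]
    if len(out_of_range):
        i = out_of_range.index[0]
        raise ValidationError(f"{path}: ALI {out_of_range.iloc[0]} outside [0, 100] at data row {i + 1}")

    traces: list[ActivityTrace] = []
    for animal_id, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("timestamp")
        if g["timestamp"].duplicated().any():
            t = g.loc[g["timestamp"].duplicated(), "timestamp"].iloc[0]
            raise ValidationError(f"{path}: duplicate (animal {animal_id}, {t}) rows")
        if bin_seconds is None:
            diffs = g["timestamp"].diff().dropna().dt.total_seconds()
            if len(diffs) == 0:
                bs = 60
            else:
                bs = int(diffs.min())
                if bs <= 0:
                    raise ValidationError(f"{path}: non-increasing timestamps for animal {animal_id}")
        else:
            bs = int(bin_seconds)
        grid = pd.date_range(g["timestamp"].iloc[0], g["timestamp"].iloc[-1], freq=f"{bs}s")
        series = g.set_index("timestamp")["ali"]
        misaligned = series.index.difference(grid)
        if len(misaligned):
            raise ValidationError(
                f"{path}: timestamp {misaligned[0]} for animal {animal_id} off the {bs}-s grid")
        values = series.reindex(grid).to_numpy(dtype=float)

        meta = {}
        for col in ("sex", "genotype"):
            if col in g.columns:
                vals = g[col].dropna()
                if len(vals):
                    meta[col] = str(vals.iloc[0])
        traces.append(
            ActivityTrace(
                animal_id=str(animal_id),
                start_time=grid[0],
                values=values,
                bin_seconds=bs,
                sex=meta.get("sex", "unknown"),
                genotype=meta.get("genotype", "WT"),
            )
        )
    return traces


def write_activity_csv(traces: Iterable[ActivityTrace], path: str | Path) -> None:
    """Write traces in the canonical long dialect (lossless round-trip).

    MISSING bins are written as rows with an empty ``ali`` field so that the
    timestamp grid — and hence the missing mask — survives the round trip.
    """
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": tr.times(),
                    "animal_id": tr.animal_id,
                    "ali": tr.values,
                    "sex": tr.sex,
                    "genotype": tr.genotype,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Schedule I/O
# ---------------------------------------------------------------------------

def read_schedule(path: str | Path) -> LightingSchedule:
    """Read a lighting schedule from CSV (``start,end,state[,lux]``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValidationError(f"{path}: JSON schedule must be a list of episode objects")
    else:
        records = pd.read_csv(path).to_dict("records")
    episodes = []
    for rec in records:
        lux = rec.get("lux")
        if lux is not None and (isinstance(lux, float) and math.isnan(lux)):
            lux = None
        episodes.append(
            LightEpisode(
                start=pd.Timestamp(rec["start"]),
                end=pd.Timestamp(rec["end"]),
                state=str(rec["state"]).upper(),
                lux=None if lux is None else float(lux),
            )
        )
    return LightingSchedule(episodes)


def write_schedule(schedule: LightingSchedule, path: str | Path) -> None:
    df = schedule.to_frame()
    df["start"] = df["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["end"] = df["end"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Metrics output
# ---------------------------------------------------------------------------

_LEADING_COLS = ["animal_id", "genotype", "sex", "phase"]


def write_metrics_table(rows: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write per-animal metric records as tidy CSV with a stable column order.

    Identification columns come first; remaining columns keep first-seen
    order.  Undefined metrics (None/NaN) are written as empty fields.
    """
    df = rows.copy() if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=_LEADING_COLS)
    cols = [c for c in _LEADING_COLS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)
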