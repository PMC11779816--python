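"""Turn raw traces into the analysis-ready forms the metrics expect.

Re-binning, the 30-min running average used to bridge daily welfare-check
gaps and draw actograms, Zeitgeber-time conversion, day segmentation and
mean daily profiles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import ActivityTrace, LightingSchedule, ValidationError

__all__ = [
    "DailyProfile",
    "DaySegments",
    "rebin",
    "running_average",
    "zt_time",
    "split_days",
    "daily_profile",
]


@dataclass
class DailyProfile:
    """Per-bin-of-day mean activity averaged over ``n_days`` days.

    ``profile[h]`` is the mean ALI of bin-of-day ``h`` (h = 0..p-1) over all
    analysed days, ignoring MISSING bins.
    """

    bins_per_day: int
    profile: np.ndarray
    n_days: int

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.size != self.bins_per_day:
            raise ValidationError("profile length must equal bins_per_day")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")


@dataclass
class DaySegments:
    """Consecutive day-length segments of a trace.

    ``full[i]`` is False for a trailing partial day, whose segment holds only
    the bins actually recorded.
    """

    segments: list[np.ndarray]
    full: list[bool]
    day_length_hours: float


def rebin(trace: ActivityTrace, new_bin_seconds: int) -> ActivityTrace:
    """Aggregate to coarser bins by averaging non-missing constituents.

    An output bin is MISSING iff all of its constituent bins are MISSING.
    ``new_bin_seconds`` must be an integer multiple of the trace bin width.
    """
    new_bin_seconds = int(new_bin_seconds)
    if new_bin_seconds % trace.bin_seconds != 0:
        raise ValidationError(
            f"new bin {new_bin_seconds}s is not a multiple of trace bin {trace.bin_seconds}s")
    k = new_bin_seconds // trace.bin_seconds
    if k == 1:
        return trace.with_values(trace.values.copy())
    n_out = math.ceil(trace.n_bins / k)
    padded = np.full(n_out * k, np.nan)
    padded[: trace.n_bins] = trace.values
    blocks = padded.reshape(n_out, k)
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(blocks).sum(axis=1)
        sums = np.nansum(blocks, axis=1)
    out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return trace.with_values(out, bin_seconds=new_bin_seconds)


def running_average(trace: ActivityTrace, window_minutes: float = 30) -> ActivityTrace:
    """Centered moving mean over non-missing values within the window.

    A bin stays MISSING only if its entire window is MISSING, so the daily
    sub-5-min welfare-check gaps are bridged by their neighbours.  Edge bins
    average over the available part of the window (no phase lag).
    """
    w = int(round(window_minutes * 60 / trace.bin_seconds))
    if w < 1:
        raise ValidationError(
            f"window of {window_minutes} min is smaller than one {trace.bin_seconds}-s bin")
    smoothed = (
        pd.Series(trace.values)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return trace.with_values(smoothed)


def zt_time(schedule: LightingSchedule, t: pd.Timestamp) -> float:
    """Zeitgeber time of ``t`` in hours: ZT0 = lights-on, modulo 24.

    Under constant conditions (DD/LL with no further lights-on events) the
    last real lights-on is projected forward on a 24-h cycle, matching the
    convention of plotting constant-condition days against the prior LD
    cycle.  Brief light pulses do not count as lights-on events.
    """
    t = pd.Timestamp(t)
    onsets = schedule.light_onsets()
    if not onsets:
        raise ValidationError("schedule has no lights-on event to anchor ZT")
    previous = [o for o in onsets if o <= t]
    anchor = previous[-1] if previous else onsets[0]
    return ((t - anchor).total_seconds() / 3600.0) % 24.0


def split_days(trace: ActivityTrace, schedule: LightingSchedule | None = None,
               day_length_hours: float = 24.0) -> DaySegments:
    """Cut the trace into consecutive ``day_length_hours`` segments.

    Segments are aligned to the trace start (the simulator and the screen
    both start recordings on a day boundary); a trailing partial day is
    kept and flagged.  ``day_length_hours`` other than 24 supports plotting
    in circadian time.
    """
    if trace.n_bins == 0:
        raise ValidationError("empty trace")
    bins_per_day = int(round(day_length_hours * 3600 / trace.bin_seconds))
    if bins_per_day < 1:
        raise ValidationError("day shorter than one bin")
    segments: list[np.ndarray] = []
    full: list[bool] = []
    for i0 in range(0, trace.n_bins, bins_per_day):
        seg = trace.values[i0: i0 + bins_per_day]
        segments.append(seg)
        full.append(seg.size == bins_per_day)
    return DaySegments(segments=segments, full=full, day_length_hours=day_length_hours)


def daily_profile(trace: ActivityTrace, bins_per_day: int = 24) -> DailyProfile:
    """Mean activity per bin-of-day over all full days, ignoring MISSING.

    The trace bin width must divide the profile bin width (24 h /
    ``bins_per_day``) so raw bins nest exactly inside profile bins.
    """
    profile_bin_s = 24 * 3600 / bins_per_day
    if profile_bin_s % trace.bin_seconds != 0:
        raise ValidationError(
            f"trace bin {trace.bin_seconds}s does not divide 24 h into {bins_per_day} bins")
    k = int(profile_bin_s // trace.bin_seconds)
    raw_per_day = bins_per_day * k
    n_days = trace.n_bins // raw_per_day
    if n_days < 1:
        raise ValidationError("trace covers no full day")
    x = trace.values[: n_days * raw_per_day].reshape(n_days, bins_per_day, k)
    counts = np.isfinite(x).sum(axis=(0, 2))
    sums = np.nansum(x, axis=(0, 2))
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DailyProfile(bins_per_day=bins_per_day, profile=profile, n_days=n_days)
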