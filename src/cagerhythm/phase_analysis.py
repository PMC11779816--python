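"""Activity-onset detection and the phase statistics built on it.

Onsets are found per day with a step-template contrast maximiser: the
candidate time maximising (mean activity over the following w_act hours)
minus (mean activity over the preceding w_rest hours).  From the onset
series come the entrainment phase, the light-pulse phase shift (Aschoff
type II, single-day comparison), jet-lag re-entrainment time, and the
double-plotted actogram matrix.

Sign convention: a positive phase shift is a DELAY (onset moves later).
Many tools use the opposite sign; this one matches the language of
light-pulse experiments at the start of the subjective night.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ingest import ActivityTrace, ValidationError
from .preprocess import rebin

__all__ = [
    "OnsetSeries",
    "PhaseShiftResult",
    "ReentrainmentResult",
    "ActogramMatrix",
    "detect_onsets",
    "phase_shift",
    "days_to_reentrain",
    "build_actogram",
    "render_actogram",
    "circular_diff_h",
]


def circular_diff_h(a: float, b: float) -> float:
    """Signed circular difference a - b in hours, mapped to (-12, 12]."""
    d = (a - b) % 24.0
    if d > 12.0:
        d -= 24.0
    return d


@dataclass
class OnsetSeries:
    """Per-day activity onsets in wall-clock hours, with template contrasts.

    ``contrast`` is the step-template height at the chosen onset (mean of
    the active window minus mean of the rest window); a contrast of 0 marks
    an unreliable onset (e.g. a constant day).
    """

    day_index: np.ndarray
    onset_h: np.ndarray
    contrast: np.ndarray
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.day_index = np.asarray(self.day_index, dtype=int)
        self.onset_h = np.asarray(self.onset_h, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if not (self.day_index.size == self.onset_h.size == self.contrast.size):
            raise ValidationError("onset series arrays must have equal length")
        if self.onset_h.size and ((self.onset_h < 0) | (self.onset_h >= 24)).any():
            raise ValidationError("onset_h must lie in [0, 24)")
        if self.contrast.size and (self.contrast < 0).any():
            raise ValidationError("contrast must be nonnegative")

    def onset_for_day(self, day: int) -> float:
        hits = np.flatnonzero(self.day_index == day)
        if hits.size == 0:
            raise ValidationError(f"no onset recorded for day {day}")
        return float(self.onset_h[hits[0]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"day": self.day_index, "onset_h": self.onset_h, "contrast": self.contrast}
        )


@dataclass(frozen=True)
class PhaseShiftResult:
    """Signed onset shift in hours, positive = delay, in (-12, 12]."""

    shift_h: float
    day_before: int
    day_after: int


@dataclass(frozen=True)
class ReentrainmentResult:
    """Days until the onset stays within tolerance of the new dark onset.

    ``days_to_reentrain`` is None when the record ends without ``stable_days``
    consecutive in-tolerance days (not reached is a value, not an error).
    """

    days_to_reentrain: int | None
    tolerance_h: float
    stable_days: int


@dataclass
class ActogramMatrix:
    """Per-day activity matrix for raster plotting (optionally double-plotted)."""

    day_rows: np.ndarray
    bins_per_row: int
    double_plotted: bool
    onsets_overlay: OnsetSeries | None = None


# ---------------------------------------------------------------------------
# Onset detection
# ---------------------------------------------------------------------------

def _sliding_means(x: np.ndarray, w_back: int, w_fwd: int) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware backward mean over [t-w_back, t) and forward mean over [t, t+w_fwd)."""
    vals = np.nan_to_num(x, nan=0.0)
    ok = np.isfinite(x).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0.0], np.cumsum(ok)])
    n = x.size
    t = np.arange(n)
    lo_b, hi_b = np.maximum(t - w_back, 0), t
    lo_f, hi_f = t, np.minimum(t + w_fwd, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cnt_b = ccnt[hi_b] - ccnt[lo_b]
        cnt_f = ccnt[hi_f] - ccnt[lo_f]
        mean_b = np.where(cnt_b > 0, (csum[hi_b] - csum[lo_b]) / np.maximum(cnt_b, 1), np.nan)
        mean_f = np.where(cnt_f > 0, (csum[hi_f] - csum[lo_f]) / np.maximum(cnt_f, 1), np.nan)
    return mean_b, mean_f


def detect_onsets(trace: ActivityTrace, day_length_h: float = 24.0,
                  w_rest_h: float = 6.0, w_act_h: float = 6.0) -> OnsetSeries:
    """Detect one activity onset per day by step-template contrast.

    For each day the onset is the bin ``t`` (scanned at trace resolution;
    windows extend into neighbouring days, shrinking at the record edges)
    maximising ``mean(x[t, t + w_act)) - mean(x[t - w_rest, t))``.  Ties
    break to the earliest bin.  The input should already be smoothed by
    :func:`~cagerhythm.preprocess.running_average`.  Days with no data are
    skipped with a warning.
    """
    x = trace.values
    bins_per_day = int(round(day_length_h / trace.bin_hours))
    if bins_per_day < 1 or trace.n_bins < bins_per_day:
        raise ValidationError("trace must cover at least one full day")
    w_back = max(1, int(round(w_rest_h / trace.bin_hours)))
    w_fwd = max(1, int(round(w_act_h / trace.bin_hours)))
    mean_b, mean_f = _sliding_means(x, w_back, w_fwd)
    score = mean_f - mean_b

    start_tod = (trace.start_time - trace.start_time.normalize()).total_seconds() / 3600.0
    days, onsets, contrasts = [], [], []
    n_days = trace.n_bins // bins_per_day
    for d in range(n_days):
        seg = score[d * bins_per_day: (d + 1) * bins_per_day]
        if not np.isfinite(seg).any():
            warnings.warn(f"animal {trace.animal_id}: day {d} has no data, onset skipped")
            continue
        j = int(np.nanargmax(seg))
        t_bin = d * bins_per_day + j
        onset_tod = (start_tod + t_bin * trace.bin_hours) % 24.0
        days.append(d)
        onsets.append(onset_tod)
        contrasts.append(max(float(seg[j]), 0.0))
    return OnsetSeries(
        day_index=np.array(days, dtype=int),
        onset_h=np.array(onsets),
        contrast=np.array(contrasts),
        method_params={
            "day_length_h": day_length_h,
            "w_rest_h": w_rest_h,
            "w_act_h": w_act_h,
            "bin_seconds": trace.bin_seconds,
        },
    )


# ---------------------------------------------------------------------------
# Phase statistics
# ---------------------------------------------------------------------------

def phase_shift(onsets: OnsetSeries, day_before: int = -1, day_after: int = 4,
                pulse_day: int = 0, free_run_period_h: float | None = None) -> PhaseShiftResult:
    """Aschoff type II phase shift: onset(day_after) - onset(day_before).

    Day indices are relative to the light-pulse day (``pulse_day`` maps
    them onto the onset series' absolute day numbering).  The circular
    difference is mapped to (-12, 12]; positive = delay.

    When the animal free-runs after the pulse (released into DD), the raw
    single-day comparison confounds the induced shift with the free-running
    drift accumulated over ``day_after`` cycles.  Passing the estimated
    free-running period removes that drift: ``day_after * (tau - 24)`` hours
    are subtracted before the circular mapping.  Default is the raw,
    uncorrected comparison.
    """
    before = onsets.onset_for_day(pulse_day + day_before)
    after = onsets.onset_for_day(pulse_day + day_after)
    raw = after - before
    if free_run_period_h is not None:
        raw -= day_after * (free_run_period_h - 24.0)
    return PhaseShiftResult(
        shift_h=circular_diff_h(raw, 0.0),
        day_before=day_before,
        day_after=day_after,
    )


def days_to_reentrain(onsets: OnsetSeries, target_onset_h: float, shift_day: int,
                      tolerance_h: float = 0.5, stable_days: int = 2) -> ReentrainmentResult:
    """Days after a schedule shift until the onset locks to the new dark onset.

    Returns the smallest ``d >= 1`` such that the onsets of days
    ``shift_day + d .. shift_day + d + stable_days - 1`` all sit within
    ``tolerance_h`` (circular distance) of ``target_onset_h``; None when
    the record ends first.
    """
    by_day = {int(d): float(o) for d, o in zip(onsets.day_index, onsets.onset_h)}
    last_day = int(onsets.day_index.max()) if onsets.day_index.size else shift_day
    d = 1
    while shift_day + d + stable_days - 1 <= last_day:
        ok = True
        for day in range(shift_day + d, shift_day + d + stable_days):
            onset = by_day.get(day)
            if onset is None or abs(circular_diff_h(onset, target_onset_h)) > tolerance_h:
                ok = False
                break
        if ok:
            return ReentrainmentResult(d, tolerance_h, stable_days)
        d += 1
    return ReentrainmentResult(None, tolerance_h, stable_days)


# ---------------------------------------------------------------------------
# Actograms
# ---------------------------------------------------------------------------

def build_actogram(trace: ActivityTrace, bins_per_row: int = 288, double: bool = True,
                   onsets: OnsetSeries | None = None,
                   day_length_h: float = 24.0) -> ActogramMatrix:
    """Assemble the per-day activity matrix behind an actogram plot.

    Row ``r`` holds day ``r`` (re-binned to ``bins_per_row`` columns); when
    double-plotted it is followed by day ``r + 1``, with the final row's
    right half MISSING.  Values are carried through unchanged apart from
    the re-binning.
    """
    target_bin_s = int(round(day_length_h * 3600 / bins_per_row))
    binned = rebin(trace, target_bin_s) if target_bin_s != trace.bin_seconds else trace
    n_days = binned.n_bins // bins_per_row
    if n_days < 1:
        raise ValidationError("trace shorter than one actogram row")
    days = binned.values[: n_days * bins_per_row].reshape(n_days, bins_per_row)
    if double:
        right = np.vstack([days[1:], np.full((1, bins_per_row), np.nan)])
        matrix = np.hstack([days, right])
    else:
        matrix = days
    return ActogramMatrix(
        day_rows=matrix,
        bins_per_row=bins_per_row,
        double_plotted=double,
        onsets_overlay=onsets,
    )


def render_actogram(matrix: ActogramMatrix, path, title: str = "",
                    cmap: str = "Greys") -> None:
    """Render an actogram matrix to PNG/SVG (darker = more active).

    The matrix, not the image, is the tested artifact; this is plotting
    convenience only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = matrix.day_rows
    n_days, n_cols = m.shape
    fig, ax = plt.subplots(figsize=(8, max(2, 0.18 * n_days)))
    ax.imshow(
        np.nan_to_num(m, nan=0.0),
        aspect="auto",
        cmap=cmap,
        interpolation="nearest",
        extent=(0, n_cols / matrix.bins_per_row * 24, n_days, 0),
    )
    if matrix.onsets_overlay is not None:
        ons = matrix.onsets_overlay
        ax.scatter(ons.onset_h % 24, ons.day_index + 0.5, s=6, color="orange", zorder=3)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("day")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
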