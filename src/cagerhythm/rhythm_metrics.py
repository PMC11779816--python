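"""Quantitative rhythm measures for binned activity series.

* Chi-square (Sokolove-Bushell) periodogram: fold the series at every
  candidate period P; the variance of the folded column means, scaled
  against the total variance, gives Qp, compared to a chi-square(P-1)
  significance line.
* Nonparametric rest-activity metrics: inter-daily stability (IS),
  intra-daily variability (IV) and relative amplitude (RA = (M10 - L5) /
  (M10 + L5)), the standard actigraphy measures of day-to-day
  reproducibility, fragmentation and amplitude.
* Activity-bout distribution, light-phase activity fraction and total
  daily activity.

Undefined metrics (zero variance, no light phase, all-zero profile) are
returned as ``None`` — an explicit marker, never silently 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ingest import ActivityTrace, LightingSchedule, ValidationError

__all__ = [
    "PeriodogramResult",
    "DisruptionMetrics",
    "BoutDistribution",
    "chi_square_periodogram",
    "interdaily_stability",
    "intradaily_variability",
    "relative_amplitude",
    "activity_bouts",
    "light_phase_activity",
    "total_activity",
]

#: Bout-length classes in minutes: 1..7 and >= 8.
BOUT_CLASSES = ("1", "2", "3", "4", "5", "6", "7", "8plus")


@dataclass
class PeriodogramResult:
    """Qp curve over candidate periods with its chi-square significance line.

    ``significant`` is the rhythmicity call: peak Qp above the
    Bonferroni-corrected chi-square quantile (alpha split across the
    candidate grid).  ``sig_line`` itself is the per-candidate
    chi-square(P-1) quantile at ``alpha``, as conventionally drawn.
    """

    candidate_periods: np.ndarray  # hours, ascending
    qp: np.ndarray
    df: np.ndarray                 # per-candidate degrees of freedom (P - 1)
    sig_line: np.ndarray
    peak_period_h: float
    max_qp: float
    alpha: float
    qp_excess: float               # max_qp minus sig_line at the peak
    significant: bool
    n_points: int                  # N' analysed at the peak

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"period_h": self.candidate_periods, "qp": self.qp, "sig_line": self.sig_line}
        )


@dataclass
class DisruptionMetrics:
    """Bundle of one animal x phase disruption measures (None = undefined)."""

    is_value: float | None
    iv_value: float | None
    ra_value: float | None
    light_phase_fraction: float | None
    total_activity_per_day: float | None
    period_h: float | None
    max_qp: float | None


@dataclass
class BoutDistribution:
    """Counts of activity bouts in the 8 length classes (1..7, >=8 min)."""

    threshold: float
    max_gap_bins: int
    class_counts: np.ndarray

    def __post_init__(self) -> None:
        self.class_counts = np.asarray(self.class_counts, dtype=int)
        if self.class_counts.size != len(BOUT_CLASSES):
            raise ValidationError(f"class_counts must have {len(BOUT_CLASSES)} entries")
        if (self.class_counts < 0).any():
            raise ValidationError("bout counts must be nonnegative")

    @property
    def n_bouts(self) -> int:
        return int(self.class_counts.sum())


# ---------------------------------------------------------------------------
# Chi-square periodogram
# ---------------------------------------------------------------------------

def chi_square_periodogram(values: np.ndarray, bin_hours: float,
                           p_min_h: float = 16.0, p_max_h: float = 32.0,
                           step_bins: int = 1, alpha: float = 0.05) -> PeriodogramResult:
    """Chi-square periodogram of an evenly binned activity series.

    For each candidate period of ``P`` bins the first ``N' = K * P`` bins
    (``K = floor(N / P)`` complete cycles) are folded into a K x P array
    with column means ``M_h`` and grand mean ``M``; then::

        Qp = N' * K * sum_h (M_h - M)^2 / sum_i (x_i - M)^2

    which under the null is approximately chi-square distributed with
    ``P - 1`` degrees of freedom.  MISSING bins are excluded from all means
    and sums with matching counts.  The peak is the candidate maximising
    ``Qp - sig_line``; ``max_qp`` is the raw Qp there.

    Raises on a constant series (the ratio is 0/0) and when the record is
    shorter than 3 cycles of the longest candidate period.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValidationError("periodogram needs at least 2 non-missing points")
    if np.nanvar(x) == 0:
        raise ValidationError("periodogram undefined for a constant series")

    p_lo = int(np.ceil(p_min_h / bin_hours))
    p_hi = int(np.floor(p_max_h / bin_hours))
    if p_lo < 2:
        raise ValidationError("p_min too small for this bin width")
    if n < 3 * p_hi:
        raise ValidationError(
            f"series of {n} bins is shorter than 3 cycles of the longest candidate ({p_hi} bins)")

    periods_bins = np.arange(p_lo, p_hi + 1, int(step_bins))
    qp = np.empty(periods_bins.size)
    dfs = np.empty(periods_bins.size, dtype=int)
    sig = np.empty(periods_bins.size)
    n_points = np.empty(periods_bins.size, dtype=int)
    for j, p in enumerate(periods_bins):
        k = n // p
        n_prime = k * p
        folded = x[:n_prime].reshape(k, p)
        col_counts = np.isfinite(folded).sum(axis=0)
        col_sums = np.nansum(folded, axis=0)
        valid_cols = col_counts > 0
        col_means = col_sums[valid_cols] / col_counts[valid_cols]
        n_valid = int(col_counts.sum())
        grand = np.nansum(folded) / n_valid
        num = float(np.sum(col_counts[valid_cols] * (col_means - grand) ** 2))
        denom = float(np.nansum((folded - grand) ** 2)) / n_valid  # sigma-hat^2
        qp[j] = num / denom
        dfs[j] = p - 1
        sig[j] = stats.chi2.ppf(1 - alpha, p - 1)
        n_points[j] = n_valid

    peak = int(np.argmax(qp - sig))
    bonferroni = stats.chi2.ppf(1 - alpha / periods_bins.size, dfs[peak])
    return PeriodogramResult(
        candidate_periods=periods_bins * bin_hours,
        qp=qp,
        df=dfs,
        sig_line=sig,
        peak_period_h=float(periods_bins[peak] * bin_hours),
        max_qp=float(qp[peak]),
        alpha=alpha,
        qp_excess=float(qp[peak] - sig[peak]),
        significant=bool(qp[peak] > bonferroni),
        n_points=int(n_points[peak]),
    )


# ---------------------------------------------------------------------------
# Nonparametric rest-activity metrics
# ---------------------------------------------------------------------------

def interdaily_stability(values: np.ndarray, bins_per_day: int = 24) -> float | None:
    """Inter-daily stability: variance of the mean daily profile over total.

    IS = [N * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2] on the
    series truncated to full days; in [0, 1] by the ANOVA decomposition,
    1 iff every day repeats identically.  Returns None when the total
    variance is zero (the ratio is undefined).
    """
    x = np.asarray(values, dtype=float)
    n_days = x.size // bins_per_day
    if n_days < 2:
        raise ValidationError("IS needs at least 2 full days")
    x = x[: n_days * bins_per_day].reshape(n_days, bins_per_day)
    counts = np.isfinite(x).sum(axis=0)
    n_valid = int(counts.sum())
    if n_valid == 0:
        return None
    grand = np.nansum(x) / n_valid
    denom = float(np.nansum((x - grand) ** 2))
    if denom == 0:
        return None
    valid = counts > 0
    col_means = np.nansum(x, axis=0)[valid] / counts[valid]
    num = float(np.sum(counts[valid] * (col_means - grand) ** 2))
    return num / denom


def intradaily_variability(values: np.ndarray) -> float | None:
    """Intra-daily variability: normalised mean squared successive difference.

    IV = [N * sum (x_i - x_{i-1})^2] / [(N - 1) * sum (x_i - xbar)^2];
    about 2 for white noise, small for consolidated rhythms.  First
    differences spanning a MISSING gap are skipped, with the counts
    adjusted to match.  Returns None when the variance is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("IV needs at least 2 points")
    finite = np.isfinite(x)
    n_valid = int(finite.sum())
    if n_valid < 2:
        return None
    diffs = np.diff(x)
    pair_ok = finite[1:] & finite[:-1]
    m = int(pair_ok.sum())
    if m == 0:
        return None
    grand = np.nansum(x) / n_valid
    var = float(np.nansum((x - grand) ** 2)) / n_valid
    if var == 0:
        return None
    msd = float(np.sum(diffs[pair_ok] ** 2)) / m
    return msd / var


def relative_amplitude(profile, active_window_h: float = 10.0,
                       rest_window_h: float = 5.0) -> float | None:
    """Relative amplitude RA = (M10 - L5) / (M10 + L5) of a daily profile.

    M10 is the maximal mean over circular 10-h windows of the profile, L5
    the minimal mean over circular 5-h windows.  Returns None when
    M10 + L5 = 0 (all-rest profile).  Invariant to positive rescaling.
    """
    prof = np.asarray(getattr(profile, "profile", profile), dtype=float)
    p = prof.size
    if not np.isfinite(prof).all():
        # profile bins with no data at all cannot support window means
        raise ValidationError("profile contains undefined bins")
    w_act = max(1, int(round(active_window_h * p / 24.0)))
    w_rest = max(1, int(round(rest_window_h * p / 24.0)))
    if w_act >= p or w_rest >= p:
        raise ValidationError("windows must be shorter than the day")

    def window_means(w: int) -> np.ndarray:
        wrapped = np.concatenate([prof, prof[: w - 1]])
        kernel = np.ones(w) / w
        return np.convolve(wrapped, kernel, mode="valid")[:p]

    m_act = float(window_means(w_act).max())
    l_rest = float(window_means(w_rest).min())
    # M10 >= overall mean >= L5 holds exactly; guard convolution round-off
    m_act = max(m_act, l_rest)
    if m_act + l_rest == 0:
        return None
    return (m_act - l_rest) / (m_act + l_rest)


# ---------------------------------------------------------------------------
# Bouts and activity totals
# ---------------------------------------------------------------------------

def activity_bouts(values: np.ndarray, threshold: float = 0.0,
                   max_gap_bins: int = 0, bin_minutes: float = 1.0) -> BoutDistribution:
    """Count activity bouts and bin their lengths into the 8 classes.

    A bout is a maximal run of bins with value > ``threshold``; runs of at
    most ``max_gap_bins`` consecutive sub-threshold bins do not break it
    (and count toward its length).  MISSING bins always break bouts.  Bout
    length is the run length in minutes; classes are 1..7 min and >= 8 min.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    active = finite & (x > threshold)
    counts = np.zeros(len(BOUT_CLASSES), dtype=int)
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return BoutDistribution(threshold, max_gap_bins, counts)

    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        gap = i - prev - 1
        gap_clean = gap <= max_gap_bins and finite[prev + 1: i].all()
        if not gap_clean:
            _tally(counts, (prev - start + 1) * bin_minutes)
            start = i
        prev = i
    _tally(counts, (prev - start + 1) * bin_minutes)
    return BoutDistribution(threshold, max_gap_bins, counts)


def _tally(counts: np.ndarray, length_min: float) -> None:
    cls = min(int(np.ceil(length_min)), 8) - 1
    counts[max(cls, 0)] += 1


def light_phase_activity(trace: ActivityTrace, schedule: LightingSchedule) -> float | None:
    """Fraction of total activity emitted during LIGHT episodes.

    None (undefined) when no LIGHT episode overlaps the trace (constant
    darkness) or the animal produced no activity at all.
    """
    light = schedule.is_light(trace.times())
    if not light.any():
        return None
    total = float(np.nansum(trace.values))
    if total == 0:
        return None
    in_light = float(np.nansum(trace.values[light]))
    return in_light / total


def total_activity(trace: ActivityTrace) -> tuple[np.ndarray, float | None]:
    """Per-day activity totals (gap-rescaled) and their mean over full days.

    Each full day's sum of non-missing ALI is scaled by the fraction of
    bins recorded, so a brief welfare-check gap does not deflate the day.
    Days with no data at all give NaN and are excluded from the mean.
    """
    bins_per_day = int(round(24 * 3600 / trace.bin_seconds))
    n_days = trace.n_bins // bins_per_day
    if n_days < 1:
        raise ValidationError("total_activity needs at least one full day")
    x = trace.values[: n_days * bins_per_day].reshape(n_days, bins_per_day)
    counts = np.isfinite(x).sum(axis=1)
    sums = np.nansum(x, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_day = np.where(counts > 0, sums * bins_per_day / np.maximum(counts, 1), np.nan)
    defined = per_day[np.isfinite(per_day)]
    mean = float(defined.mean()) if defined.size else None
    return per_day, mean
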