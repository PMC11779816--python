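"""Simulate minute-binned home-cage activity over a full circadian screen.

The generator emulates the statistical structure the analysis assumes:
nocturnal activity gated by a circadian oscillator whose period depends on
the lighting condition (entrained ~24 h, free-running ~23.5 h in DD,
lengthened ~25.1 h in LL), negative masking by light, a light-pulse-induced
phase delay, rate-limited re-entrainment after a 6-h schedule advance
(~1 h/day), zero-inflated gamma minute noise, one daily 5-min missing-data
gap from welfare checks, and an arrhythmic clock-deficient mode whose
activity is light-driven only (no endogenous rhythm in DD).

The default protocol is the 10-week screen: 1 week 12:12 LD, 10 days LD
after a 6-h advance, 10 days DD, 2 weeks LD re-entrainment, a 2-h light
pulse at ZT14-16, 10 days DD, 10 days LL.

Phase bookkeeping: the internal clock is tracked as a deviation D(t) =
phase - Zeitgeber time, in hours.  Entrained LD days hold D constant and
step it toward 0 by the re-entrainment rate rho once per day (the first
day after a schedule change is uncorrected, so the full shift is visible
in that day's onset).  Constant conditions drift D at 24/tau - 1 h per
hour.  The light pulse subtracts the delay from D at pulse end.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import (
    DARK,
    LIGHT,
    ActivityTrace,
    LightEpisode,
    LightingSchedule,
    ProtocolPhase,
    ValidationError,
)

__all__ = [
    "AnimalParams",
    "CohortSpec",
    "Protocol",
    "CohortResult",
    "build_protocol",
    "simulate_animal",
    "simulate_cohort",
]

_DEFAULT_PHASE_DAYS = (
    ("LD_BASELINE", 7),
    ("JETLAG_LD", 10),
    ("DD", 10),
    ("LD_REENTRAIN", 14),
    ("LP", 1),
    ("DD_POST_LP", 10),
    ("LL", 10),
)

#: Parameter overrides applied to arrhythmic (Cry-deficient-like) animals:
#: no endogenous oscillator, weaker light suppression, more around-the-clock
#: baseline activity, more zero-inflation churn (short fragmented bouts) and
#: ultradian on/off bursting that fragments activity at the hourly scale.
ARRHYTHMIC_OVERRIDES = dict(arrhythmic=True, mask_light=0.5, baseline=4.0,
                            zero_inflation=0.65, burst_dwell_min=45.0)


@dataclass
class AnimalParams:
    """Per-animal generative parameters.

    Periods are the condition-dependent targets reported for C57BL/6J-like
    mice: entrained 24.0 h, free-running 23.5 h in DD, lengthened 25.1 h in
    LL.  ``reentrain_rate_h_per_day`` is the rate-limited phase correction
    under LD (1 day of adjustment per hour of shift); ``lp_delay_h`` the
    instantaneous delay injected by a ZT14-16 light pulse.  ``mask_light``
    multiplies activity while lights are on (negative masking); in LL it
    applies around the clock (amplitude reduction).  ``onset_lead_h`` is
    the arrhythmic genotype's light-driven activity lead before dark onset.
    ``burst_dwell_min`` > 0 multiplies the active drive by a mean-preserving
    random on/off (telegraph) process with that mean dwell, emulating the
    ultradian fragmentation of clock-deficient activity.
    """

    animal_id: str = "A01"
    genotype: str = "WT"
    sex: str = "M"
    seed: int = 0
    tau_ld_h: float = 24.0
    tau_dd_h: float = 23.5
    tau_ll_h: float = 25.1
    gate_fraction: float = 0.5
    amp: float = 20.0
    baseline: float = 1.0
    mask_light: float = 0.2
    reentrain_rate_h_per_day: float = 1.0
    lp_delay_h: float = 1.3
    noise_shape: float = 1.5
    noise_scale: float = 1.0
    zero_inflation: float = 0.5
    arrhythmic: bool = False
    onset_lead_h: float = 1.0
    burst_dwell_min: float = 0.0  # 0 disables the ultradian on/off burst process
    burst_duty: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.gate_fraction < 1):
            raise ValidationError("gate_fraction must be in (0, 1)")
        if not (0 <= self.mask_light <= 1):
            raise ValidationError("mask_light must be in [0, 1]")
        if not (0 <= self.zero_inflation < 1):
            raise ValidationError("zero_inflation must be in [0, 1)")
        for name in ("amp", "baseline", "reentrain_rate_h_per_day", "noise_shape", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")


@dataclass
class CohortSpec:
    """Cohort layout: who is simulated, under which protocol, from which seed."""

    n_animals: int = 12
    genotypes: tuple[str, ...] | None = None  # None -> all WT
    start_date: str = "2024-01-01"
    seed: int = 0
    daily_check_tod_h: float = 10.0
    daily_check_minutes: int = 5
    jitter_tau_sd: float = 0.05
    jitter_amp_sd: float = 1.0
    sex_activity_factor: float = 1.0  # 1.0 = sex effects off
    sex_tau_offset_h: float = 0.0
    protocol: "Protocol | None" = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if self.genotypes is not None and len(self.genotypes) != self.n_animals:
            raise ValidationError("genotypes must list one entry per animal")

    def resolved_protocol(self) -> "Protocol":
        return self.protocol if self.protocol is not None else build_protocol(self.start_date)


@dataclass
class Protocol:
    """Fully expanded lighting protocol shared by a cohort."""

    start_time: pd.Timestamp          # trace start (a day boundary)
    n_days: int
    phases: list[ProtocolPhase]
    light_intervals: list[tuple[float, float]]  # hours since start
    lights_on_offset: np.ndarray      # per day, hours from day start to lights-on
    mode_by_day: list[str]            # LD / LP / DD / LL
    shift_day: int | None
    advance_h: float
    pulse_day: int | None
    pulse_h: tuple[float, float] | None  # hours since start
    schedule: LightingSchedule
    target_onset_tod: float           # dark-onset time-of-day after the shift

    def phase(self, label: str) -> ProtocolPhase | None:
        for ph in self.phases:
            if ph.label == label:
                return ph
        return None


def build_protocol(start_date: str = "2024-01-01", lights_on_h: float = 7.0,
                   advance_h: float = 6.0,
                   phase_days: tuple[tuple[str, int], ...] = _DEFAULT_PHASE_DAYS) -> Protocol:
    """Expand the screen into day-granular phases and explicit light episodes.

    The trace starts at the post-advance lights-on time (``lights_on_h -
    advance_h``) so that every day after the jet-lag shift begins exactly
    at lights-on; baseline days have lights-on ``advance_h`` hours into the
    day.  The light pulse sits at ZT14-16 of the LP day.
    """
    labels = [lb for lb, _ in phase_days]
    if "LP" in labels:
        i = labels.index("LP")
        if i == 0 or labels[i - 1] not in ("LD_REENTRAIN", "LD_BASELINE", "DD"):
            raise ValidationError("LP phase needs a preceding LD/DD context")

    phases: list[ProtocolPhase] = []
    day = 0
    for label, nd in phase_days:
        phases.append(ProtocolPhase(label, day, day + nd))
        day += nd
    n_days = day
    day_start_tod = (lights_on_h - advance_h) % 24.0

    offsets = np.zeros(n_days)
    modes: list[str] = []
    light_intervals: list[tuple[float, float]] = []
    shift_day = None
    pulse_day = None
    pulse_h = None
    seen_shift = False
    for ph in phases:
        for d in range(ph.start_day, ph.end_day):
            if ph.label == "LD_BASELINE":
                o = advance_h
                modes.append("LD")
                light_intervals.append((24 * d + o, 24 * d + o + 12))
            elif ph.label in ("JETLAG_LD", "LD_REENTRAIN"):
                o = 0.0
                modes.append("LD")
                light_intervals.append((24.0 * d, 24.0 * d + 12))
                if ph.label == "JETLAG_LD" and not seen_shift:
                    shift_day = d
                    seen_shift = True
            elif ph.label == "LP":
                o = 0.0
                modes.append("LP")
                light_intervals.append((24.0 * d, 24.0 * d + 12))
                pulse_day = d
                pulse_h = (24.0 * d + 14, 24.0 * d + 16)
                light_intervals.append(pulse_h)
            elif ph.label in ("DD", "DD_POST_LP"):
                o = 0.0
                modes.append("DD")
            elif ph.label == "LL":
                o = 0.0
                modes.append("LL")
                light_intervals.append((24.0 * d, 24.0 * (d + 1)))
            offsets[d] = o

    # merge adjacent LL day-intervals into one episode span
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(light_intervals):
        if merged and abs(merged[-1][1] - lo) < 1e-9:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))

    start_time = pd.Timestamp(start_date).normalize() + pd.Timedelta(hours=day_start_tod)
    episodes: list[LightEpisode] = []
    cursor = 0.0
    for lo, hi in merged:
        if lo > cursor:
            episodes.append(LightEpisode(
                start_time + pd.Timedelta(hours=cursor),
                start_time + pd.Timedelta(hours=lo), DARK, 0.0))
        episodes.append(LightEpisode(
            start_time + pd.Timedelta(hours=lo),
            start_time + pd.Timedelta(hours=hi), LIGHT, 100.0))
        cursor = hi
    if cursor < 24.0 * n_days:
        episodes.append(LightEpisode(
            start_time + pd.Timedelta(hours=cursor),
            start_time + pd.Timedelta(hours=24.0 * n_days), DARK, 0.0))

    return Protocol(
        start_time=start_time,
        n_days=n_days,
        phases=phases,
        light_intervals=merged,
        lights_on_offset=offsets,
        mode_by_day=modes,
        shift_day=shift_day,
        advance_h=advance_h,
        pulse_day=pulse_day,
        pulse_h=pulse_h,
        schedule=LightingSchedule(episodes),
        target_onset_tod=(day_start_tod + 12.0) % 24.0,
    )


# ---------------------------------------------------------------------------
# Single-animal simulation
# ---------------------------------------------------------------------------

def _step_toward_zero(d: float, rho: float) -> float:
    return math.copysign(max(abs(d) - rho, 0.0), d) if d != 0 else 0.0


def _telegraph(rng: np.random.Generator, n: int, dwell_min: float, duty: float) -> np.ndarray:
    """Random on/off process with mean cycle 2*dwell and on-fraction ``duty``."""
    mean_on = 2.0 * dwell_min * duty
    mean_off = 2.0 * dwell_min * (1.0 - duty)
    state = np.empty(n)
    on = rng.random() < duty
    i = 0
    while i < n:
        dwell = rng.exponential(mean_on if on else mean_off)
        j = min(n, i + max(1, int(round(dwell))))
        state[i:j] = 1.0 if on else 0.0
        on = not on
        i = j
    return state


def _deviation_by_minute(params: AnimalParams, proto: Protocol) -> np.ndarray:
    """Clock deviation D(t) = phase - ZT, per minute over the whole record."""
    n_days = proto.n_days
    u = (np.arange(1440) + 0.5) / 60.0  # hour-of-day at bin centres
    out = np.empty(n_days * 1440)
    rho = params.reentrain_rate_h_per_day
    r_dd = 24.0 / params.tau_dd_h - 1.0
    r_ll = 24.0 / params.tau_ll_h - 1.0
    d_cur = 0.0
    first_ld_day = False  # next LD day is the first after a transition: no correction
    for d in range(n_days):
        mode = proto.mode_by_day[d]
        i0 = d * 1440
        if mode in ("LD", "LP"):
            if proto.shift_day is not None and d == proto.shift_day:
                # schedule advanced: ZT jumps forward, the clock lags behind
                d_cur -= proto.advance_h
                d_cur = (d_cur + 12.0) % 24.0 - 12.0
            elif first_ld_day:
                pass  # full deviation visible on the first shifted/relit day
            else:
                d_cur = _step_toward_zero(d_cur, rho)
            first_ld_day = False
            if mode == "LD":
                out[i0: i0 + 1440] = d_cur
            else:
                # LP day: LD until dark onset, then released into DD; the
                # pulse applies its delay instantaneously at pulse end.
                dark_u = proto.lights_on_offset[d] + 12.0
                pulse_end_u = proto.pulse_h[1] - 24.0 * d
                day_dev = np.full(1440, d_cur)
                drifting = u >= dark_u
                day_dev[drifting] = d_cur + r_dd * (u[drifting] - dark_u)
                day_dev[u >= pulse_end_u] -= params.lp_delay_h
                out[i0: i0 + 1440] = day_dev
                d_cur = d_cur + r_dd * (24.0 - dark_u) - params.lp_delay_h
        else:
            rate = r_dd if mode == "DD" else r_ll
            out[i0: i0 + 1440] = d_cur + rate * u
            d_cur += rate * 24.0
            first_ld_day = True
    return out


def simulate_animal(params: AnimalParams, spec: CohortSpec) -> tuple[ActivityTrace, LightingSchedule]:
    """Generate one animal's minute-binned ALI trace over the protocol.

    Expected activity is ``baseline + amp * gate`` with the gate driven by
    the internal clock (subjective night) — or, for arrhythmic animals, by
    the lights alone (dark-active with an ``onset_lead_h`` head start, flat
    in constant conditions).  Lights-on multiplies activity by
    ``mask_light``.  Emitted ALI is a zero-inflated gamma draw with that
    mean, clipped to [0, 100]; fully reproducible from ``params.seed``.
    """
    proto = spec.resolved_protocol()
    n_min = proto.n_days * 1440
    u = np.tile((np.arange(1440) + 0.5) / 60.0, proto.n_days)  # hour of day
    day_of = np.repeat(np.arange(proto.n_days), 1440)
    t_h = day_of * 24.0 + u

    offsets = proto.lights_on_offset[day_of]
    mode_arr = np.array(proto.mode_by_day)[day_of]

    if params.arrhythmic:
        drive = np.where(mode_arr == "LD", 0.0, params.gate_fraction)
        ld_like = (mode_arr == "LD") | (mode_arr == "LP")
        lead_start = offsets + 12.0 - params.onset_lead_h
        in_night = ((u - lead_start) % 24.0) < (12.0 + params.onset_lead_h)
        drive = np.where(ld_like, in_night.astype(float), drive)
    else:
        zt = (u - offsets) % 24.0
        dev = _deviation_by_minute(params, proto)
        phase = (zt + dev) % 24.0
        drive = (((phase - 12.0) % 24.0) < 24.0 * params.gate_fraction).astype(float)

    rng = np.random.default_rng(params.seed)
    if params.burst_dwell_min > 0:
        drive = drive * _telegraph(rng, n_min, params.burst_dwell_min,
                                   params.burst_duty) / params.burst_duty
    mu = params.baseline + params.amp * drive

    light = np.zeros(n_min, dtype=bool)
    for lo, hi in proto.light_intervals:
        light |= (t_h >= lo) & (t_h < hi)
    mu = np.where(light, mu * params.mask_light, mu)

    if params.noise_scale == 0:
        values = mu.copy()
        if params.zero_inflation > 0:
            values[rng.random(n_min) < params.zero_inflation] = 0.0
    else:
        keep = 1.0 - params.zero_inflation
        scale = params.noise_scale * mu / (keep * params.noise_shape)
        values = rng.gamma(params.noise_shape, scale)
        values[rng.random(n_min) < params.zero_inflation] = 0.0
    values = np.clip(values, 0.0, 100.0)

    if spec.daily_check_minutes > 0:
        day_start_tod = (proto.start_time - proto.start_time.normalize()).total_seconds() / 3600.0
        check_u = (spec.daily_check_tod_h - day_start_tod) % 24.0
        j0 = int(round(check_u * 60))
        for d in range(proto.n_days):
            values[d * 1440 + j0: d * 1440 + j0 + spec.daily_check_minutes] = np.nan

    trace = ActivityTrace(
        animal_id=params.animal_id,
        start_time=proto.start_time,
        values=values,
        bin_seconds=60,
        sex=params.sex,
        genotype=params.genotype,
    )
    return trace, proto.schedule


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Simulated traces and schedules plus the ground truth for recovery tests."""

    animals: list[tuple[ActivityTrace, LightingSchedule]]
    ground_truth: pd.DataFrame
    protocol: Protocol

    @property
    def traces(self) -> list[ActivityTrace]:
        return [tr for tr, _ in self.animals]


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    """Simulate a cohort with deterministic per-animal seeds and jitter.

    Per-animal seeds derive from the shared seed; tau and amplitude get a
    small gaussian jitter (configurable; sd 0 reproduces the shared values
    exactly).  Sexes alternate M/F within each genotype.  The ground-truth
    table records the generative period per condition, the injected
    light-pulse delay, the shift day and the closed-form expected
    re-entrainment duration.
    """
    proto = spec.resolved_protocol()
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_animals)
    genotypes = list(spec.genotypes) if spec.genotypes is not None else ["WT"] * spec.n_animals

    animals: list[tuple[ActivityTrace, LightingSchedule]] = []
    truth_rows = []
    sex_counter: dict[str, int] = {}
    for i in range(spec.n_animals):
        geno = genotypes[i]
        k = sex_counter.get(geno, 0)
        sex_counter[geno] = k + 1
        sex = "M" if k % 2 == 0 else "F"
        params = AnimalParams(
            animal_id=f"{geno}_{i + 1:02d}",
            genotype=geno,
            sex=sex,
            seed=int(seeds[i]),
        )
        if geno != "WT":
            params = replace(params, **ARRHYTHMIC_OVERRIDES)
        tau_dd = params.tau_dd_h + rng.normal(0.0, spec.jitter_tau_sd)
        tau_ll = params.tau_ll_h + rng.normal(0.0, spec.jitter_tau_sd)
        amp = max(params.amp + rng.normal(0.0, spec.jitter_amp_sd), 1.0)
        if sex == "F":
            amp *= spec.sex_activity_factor
            tau_dd += spec.sex_tau_offset_h
            tau_ll += spec.sex_tau_offset_h
        params = replace(params, tau_dd_h=tau_dd, tau_ll_h=tau_ll, amp=amp)

        trace, schedule = simulate_animal(params, spec)
        animals.append((trace, schedule))
        arr = params.arrhythmic
        truth_rows.append(
            {
                "animal_id": params.animal_id,
                "genotype": geno,
                "sex": sex,
                "seed": params.seed,
                "arrhythmic": arr,
                "tau_ld_h": np.nan if arr else 24.0,  # entrained to the zeitgeber
                "tau_dd_h": np.nan if arr else tau_dd,
                "tau_ll_h": np.nan if arr else tau_ll,
                "lp_delay_h": np.nan if arr else params.lp_delay_h,
                "shift_day": proto.shift_day,
                "amp": amp,
            }
        )
    return CohortResult(animals=animals, ground_truth=pd.DataFrame(truth_rows), protocol=proto)
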