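# Methods

## Data model

Activity is a per-animal, uniformly binned series of Animal Locomotion
Index (ALI) percentages in [0, 100] (default 1-min bins).  Missing bins
are a first-class marker (NaN), never zero: daily welfare checks remove
the cage from the sensor for a few minutes and must not register as
immobility.  Every metric excludes missing bins from its sums and means
with matching count corrections rather than imputing.

Timestamps are wall-clock and timezone-naive; all phase arithmetic is in
hours since trace start.  Day-granular operations (daily profiles,
actogram rows, onset days) segment the trace into 24-h blocks from the
trace start; the bundled simulator starts recordings on a day boundary
aligned with the post-shift lights-on, and Zeitgeber time (ZT0 =
lights-on) is computed from the governing lights-on event, projected
forward on a 24-h cycle under constant conditions.  Light episodes
shorter than 6 h (light pulses) do not count as lights-on events.

## Preprocessing

A centred 30-min running average (shrinking at the record edges, so no
phase lag is injected into onset estimates) bridges the sub-5-min daily
gaps and smooths traces for actograms and onset detection.  The
disruption metrics are computed from the **raw** series re-binned to 1 h:
the smoothing exists to handle gaps and plotting, and hourly bins are the
conventional resolution for IS/IV; both choices are configurable.

Metrics are computed per protocol phase on the first 7 consecutive full
days of the phase.  A phase is analysable if at least 5 full days exist
(tolerating truncated records); otherwise the metric row is emitted with
explicit undefined markers and a logged warning — undefined is never
silently 0.

## Chi-square periodogram

For each candidate period of `P` bins the first `N' = K·P` bins (`K =
floor(N/P)` complete cycles) are folded into a K×P array; with column
means `M_h` and grand mean `M`,

    Qp = N' · K · Σ_h (M_h − M)² / Σ_i (x_i − M)²,

approximately χ²(P−1) under the white-noise null.  A noiseless periodic
signal attains the maximum Qp = N'.  The candidate grid is 16–32 h in
1-bin steps on 6-min re-binned data (0.1 h resolution), wide enough for
the >25-h periods seen under constant light; the record must cover at
least 3 cycles of the longest candidate.  Constant input raises an error
(the statistic is 0/0).

Three significance-related quantities are reported:

* `sig_line`: the per-candidate χ²(P−1) quantile at α = 0.05, the line
  conventionally drawn on periodogram plots.
* `max_qp` (raw peak Qp, the headline robustness number) and `qp_excess`
  = peak Qp − sig_line, since conventions differ on whether "Max Qp" is
  baseline-subtracted; the peak is the candidate maximising Qp −
  sig_line, so the χ² baseline's slow growth with P does not bias the
  period estimate upward.
* `significant`: the rhythmicity call, using a Bonferroni-corrected
  quantile (α divided by the number of candidates).  Without the
  correction a ~160-candidate scan calls nearly every noise trace
  rhythmic.

The screen makes the boolean rhythmicity call on **hourly** bins while
estimating the period on the 0.1-h grid.  The χ² calibration assumes
noise uncorrelated at the bin scale; real (and simulated) activity has
minute-scale bout structure whose autocorrelation spans many 6-min bins
and fattens the upper tail of Qp, producing spurious "significant" calls
on arrhythmic data.  At hourly bins — the classical formulation of the
statistic — the correlation is largely averaged out and the call cleanly
separates rhythmic from arrhythmic animals.

## Nonparametric disruption metrics

IS, IV and RA follow the standard actigraphy definitions given in the
README.  IS lies in [0, 1] by the ANOVA decomposition (no post-hoc
clipping); IV ≈ 2 for white noise; both are invariant to affine rescaling
of the activity values, RA to positive rescaling of the profile.  With
missing data, IS weights each bin-of-day mean by its observation count
and IV skips first differences that span a gap, with the counts adjusted
to match.  Zero-variance input yields the undefined marker.

Light-phase activity is the fraction of summed ALI emitted during LIGHT
episodes (undefined under DD or for an all-zero trace).  Total activity
per day rescales each day's sum by the fraction of bins recorded, so a
5-min welfare gap does not deflate the day.

Bouts: the underlying data stream does not come with a bout definition,
so the module's explicit choice is a maximal run of minutes with ALI
strictly above θ = 0, with interruptions of at most g = 0 sub-threshold
minutes bridged (both config-exposed and recorded in output metadata);
missing bins always break bouts.  Lengths are pooled into eight classes
(1–7 min, ≥ 8 min), matching the eight-level bout factor used in screen
analyses.

## Onsets and phase statistics

Onset detection is a step-template contrast maximiser: for each day, the
candidate time t (scanned at bin resolution, windows wrapping into
neighbouring days and shrinking at the record edges) maximising
mean(activity in [t, t+6 h)) − mean(activity in [t−6 h, t)).  The
contrast at the maximum is reported; zero contrast flags an unreliable
onset.  Ties break to the earliest bin.  The screen scans 6-min re-binned
smoothed traces; on simulated LD cohorts the median onset error is below
one bin.  Onsets are reported in external (wall-clock) time, which is
exact under LD and a conventional choice under DD/LL.

The light-pulse phase shift is the Aschoff type II single-day comparison,
onset(Day +4) − onset(Day −1) relative to the pulse day, circularly
mapped to (−12, 12] with **positive = delay** (the convention is often
opposite; it is chosen to match the language of early-night light
pulses).  When animals free-run in DD after the pulse, the raw comparison
confounds the induced shift with `day_after · (τ − 24)` hours of drift —
about −2 h over four days at τ = 23.5 h, i.e. the raw number cannot equal
the induced delay.  `phase_shift` therefore accepts a free-running-period
drift correction, which the screen applies by default using the period
estimated from the post-pulse DD phase itself; the uncorrected comparison
remains available (and is the bare operation's default).  A
regression-of-onsets alternative was considered and rejected as the
default to keep the headline number a transparent two-onset comparison.

Re-entrainment after a schedule shift is the smallest d ≥ 1 such that the
onsets of days shift_day+d … shift_day+d+c−1 all lie within ε of the new
dark onset (circular distance); defaults ε = 0.5 h, c = 2, under which a
noiseless 1 h/day corrector re-entrains to a 6-h advance in
ceil((6 − ε)/ρ) = 6 days.  "Not reached" is a value, not an error.

## Synthetic cohorts

The generator produces the stated screen (7 d LD, 10 d LD after a 6-h
advance, 10 d DD, 14 d LD, a 2-h pulse at ZT14–16, 10 d DD, 10 d LL;
62 days) and emulates:

* a circadian gate (active half of the cycle, subjective night) driven by
  an internal phase tracked as a deviation D = phase − ZT.  Entrained LD
  days hold D constant, stepping it toward 0 once per day at ρ = 1 h/day;
  the first day after a schedule change is uncorrected, so the full shift
  is visible in that day's onset and deviations after a 6-h advance run
  6, 5, 4, 3, 2, 1, 0 on successive days.  Constant conditions drift D at
  24/τ − 1 per hour (τ_DD = 23.5 h, τ_LL = 25.1 h defaults);
* negative masking: lights-on multiplies expected activity by
  mask_light = 0.2.  LL is the same period-lengthened gate with the mask
  applied around the clock (weaker rhythms by amplitude reduction, no
  explicit arrhythmia switch);
* the pulse applies an instantaneous 1.3-h delay to the phase at pulse
  end;
* minute noise: zero-inflated gamma (shape 1.5, zero probability 0.5)
  with mean baseline + amp·gate (baseline 1, amp 20 ALI), clipped to
  [0, 100]; one 5-min missing gap per day at a fixed time of day;
* per-animal seeds derived from the shared seed, and small gaussian
  jitter on τ (sd 0.05 h) and amplitude (sd 1 ALI), chosen to match the
  reported between-animal SEMs of free-running period estimates;
* an arrhythmic (cryptochrome-knockout-like) mode: no endogenous
  oscillator; under LD activity is light-driven only, dark-active with a
  1-h lead before dark onset (earlier onsets) and weaker light
  suppression (mask 0.5) over a higher around-the-clock baseline (4 ALI);
  in constant conditions the drive is flat.  Fragmentation is modelled by
  raised zero-inflation (0.65) plus a mean-preserving random on/off
  (telegraph) burst process with 45-min mean dwell.  The dwell is a free
  choice: minute-scale zero inflation alone averages out of hourly bins
  and cannot reproduce the elevated IV of clock-deficient animals, while
  sub-hour bursting is the canonical picture of fragmented rest-activity
  behaviour.

Re-entrainment is modelled as rate-limited phase correction rather than a
phase-response curve, because only the aggregate ~1 day/hour rate is
identified by onset data; a PRC would add unidentifiable parameters.
Sex is carried as a covariate with optional effect multipliers (activity
level, τ offset) that default to off.

What a green test establishes — and does not.  The simulator reproduces
the gating, masking, drift, noise and missingness structure the metrics
assume, so recovery tests validate the estimators against a known ground
truth.  It does not emulate ultradian feeding/grooming structure in
wild-type animals, cage-change or thermoregulatory effects, oestrous
modulation, electrode-level spatial detail, or gradual LL-induced
arrhythmia; agreement on simulation is therefore necessary, not
sufficient, for fidelity on real cage data.

## Numerical conventions

* Undefined metrics are `None` in memory and empty fields in CSV output —
  never silently 0 or NaN.
* Periodogram peaks report the grid candidate (no sub-grid
  interpolation); ties in onset scanning and peak selection break to the
  earlier candidate (numpy argmax convention).
* Re-binning requires an integer bin multiple; an output bin is missing
  only if all constituents are; totals are conserved on gap-free traces.
* All randomness flows from explicit integer seeds; identical config +
  seed reproduces byte-identical output files.

## Limitations

Group-level inference (ANOVA, rank tests, power analysis) is out of
scope by design.  No Lomb–Scargle or wavelet periodograms, no cosinor
fit, no activity-offset or alpha/rho analysis, no
masking-vs-entrainment decomposition.  The chi-square periodogram's χ²
calibration is approximate for autocorrelated data even at hourly bins;
the Bonferroni call is conservative by construction.
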