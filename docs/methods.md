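# Methods

## The protocol in one paragraph

`wheelergo` implements the analysis chain of a standardized, individualized
wheelchair-specific exercise-capacity protocol on a dual-roller ergometer.
Four tests run in fixed order — isometric strength, 10 s sprint, 30 s
Wingate (WAnT), graded exercise test (GXT) — and each test's resistance is
prescribed from the previous test's outcome through two empirical per-kg
regressions (`P30_est = 0.51·F_iso − 0.18`, `POpeak_est = 0.67·P30 + 0.11`,
established in wheelchair users with spinal cord injury) and a rolling
power balance `P = μ·m_total·g·v`. The package extracts the per-test
outcomes from raw torque/velocity traces, evaluates protocol validity,
reconstructs the scaling regressions at cohort level with Theil-Sen
estimators, and ships a synthetic trace generator so the whole chain is
testable without instrument data.

## Signal model

Traces carry per-side wheel torque `M` (N·m) and linear wheel velocity `v`
(m·s⁻¹) at 100 Hz. Handrim-effective force is `F = M/r_r`, power is
`PO = (M/r_w)·v`; per side `PO = F·(r_r/r_w)·v` holds as an algebraic
identity and is enforced by tests to round-off. Outcome conventions: force
and velocity are side *averages*, power is the side *sum*.

All torque/velocity channels pass a 4th-order low-pass Butterworth filter
(10 Hz cut-off) before metric extraction. Filtering is **zero-phase**
(`scipy.signal.sosfiltfilt`, odd-reflection edge padding of three filter
lengths): the headline outcomes are rolling-window means whose window
*positions* must not be biased by filter lag, and zero-phase application
removes lag at the cost of doubling the effective order. Velocities are
clipped at zero after filtering (rollers cannot turn backwards; zero-phase
filtering of a standstill start can undershoot by millimetres per second).
Heart rate is never filtered and is step-interpolated onto the trace clock.

Rolling windows are sample-count windows (`round(window·rate)` samples),
full windows only, stride one sample, ties broken to the earliest window.
The implementation uses a cumulative sum (O(n)); the earliest window within
1e-12 relative of the maximum is reported so that float drift cannot move a
tie away from its first occurrence. Analysis windows anchor at
`test_start` (protocol trigger from the sidecar; when absent, onset is the
first sample with side-averaged velocity above 0.1 m·s⁻¹, or force above
5 N for isometric trials). A GXT's duration is counted as
`last sample − test_start + one sample period`, so a recording of exactly
*n* whole seconds reports *n* seconds.

## Outcome definitions

* **F_iso** — highest 3 s rolling mean of side-averaged force, best of up
  to three 5 s trials; trials shorter than one window are unusable, and a
  participant with no usable trial yields no result (never zero).
* **Sprint** — mean/peak of summed power and side-averaged velocity over
  `[test_start, test_start+10 s)`; the sprint with the highest one-sample
  peak velocity is kept.
* **WAnT** — P30 (30 s mean), six successive 5 s interval means (P5 = their
  maximum), one-sample peak power, and rate of fatigue
  `RF = (first − last)/first·100%` where "first"/"last" are the first and
  last of the six interval means (the natural reading of an otherwise
  undefined start/end). Equal-length intervals make P30 the exact mean of
  the six interval means.
* **GXT** — POpeak as the highest 30 s rolling mean of summed power,
  duration to termination (recording stops when the target velocity cannot
  be held), one-sample peak heart rate, and overall RPE as the half-up
  rounded average of the central and peripheral ratings (1–10). Half-up is
  forced by the reference cohort's printed values (6.5→7, 7.5→8) and by its
  count of sub-8 overall ratings.

## Prescriptions

`μ_WAnT = P30_est/(2.0·m_total·g)` with g = 9.81 m·s⁻²: the printed form
of the equation divides by total mass "in N", which is read as total
*weight* — power over velocity is a force, and force over weight is the
dimensionless μ the ergometer expects (consistent with the gym-court value
0.012 used for sprints). The GXT stage schedule starts at 20% of
POpeak_est and climbs 8% per minute ("10% of the difference between
starting load and POpeak_est"), reaching 100% at stage 11 so that a
correctly estimated participant exhausts around minute 10; schedules are
built to 15 stages by default so over-performers remain representable.
Estimates are kept at full precision; rounding half-up to whole watts
happens only in reports.

## Validity rules

WAnT: valid iff one-sample peak velocity ≤ 3.00 m·s⁻¹ (3.01 is invalid)
and mean velocity exceeds 0.5 m·s⁻¹ (an operationalization of "could
accelerate"; no threshold is stated anywhere). GXT: primary criterion is
duration in [480 s, 720 s], inclusive at both ends (forced by the
reference cohort's flagging of 480 s and 720 s rows as valid). Secondary:
peak HR ≥ round_half_up(0.95·(200 − age)) and overall RPE ≥ 8. The
literal "over" readings of the secondary criteria contradict the reference
cohort's own failure counts (a strict > on unrounded HR thresholds flags
five participants instead of two); the ≥-with-rounding rules reproduce the
counts exactly and are documented as operational choices, not as the
original authors' code.

## Cohort statistics

Percent deviation is `Δ = 100·(meas − est)/est`; the ±20% boundaries flag
`|Δ| > 20` strictly. The bundled cohort table carries the study's printed
Δ columns, and flag counts on that fixture use them: they were computed
from unrounded raw data, and recomputing from the rounded printed columns
moves one Wingate value from +21 to exactly +20.0, which a strict rule
would drop. Estimated-vs-measured comparisons report the mean ± SD percent
deviation and a paired test gated by Shapiro-Wilk at 0.05 (non-normal →
Wilcoxon signed-rank, else paired t); both p-values are always reported,
the gate only selects the headline.

Theil-Sen fits use `scipy.stats.theilslopes(method="joint")` — slope is
the median of all pairwise slopes, intercept the median of
`y − slope·x` — with an independent brute-force pairwise oracle in the
test suite. The slope p-value comes from the Kendall rank-correlation
test, the intercept p-value from a Wilcoxon signed-rank test of the
residual median against zero. Explained variance of a non-least-squares
line is not uniquely defined; both the squared Pearson correlation and
`1 − SS_res/SS_tot` around the Theil-Sen line are reported. Per-kg
regressors are absolute values divided by body mass, never the table's
rounded per-kg cells; missing tests drop listwise per analysis (n = 19,
20, 17 on the bundled cohort).

## Synthetic-data generator

Population defaults are the study conditions: body mass N(72, 11) kg
clipped to [45, 110], age N(23, 2) y in 18–30, isometric strength
N(2.9, 0.8) N·kg⁻¹ clipped to [0.8, 5.0], balanced sexes, resting HR
N(65, 8) bpm, maximal HR 200 − age, push frequency N(1.5, 0.15) Hz. Latent
capacities follow the generating regressions above with Gaussian per-kg
noise σ₁ = σ₂ = 0.05 W·kg⁻¹ by default, rejection-resampled positive.
Sensor noise is Gaussian per sample (0.2 N·m torque, 0.01 m·s⁻¹ velocity).
Identical seed and configuration give bit-identical traces.

Pushing is a half-rectified sinusoidal drive force scaled by a linear
force–velocity factor `max(0, 1 − v/v_limit)` with `v_limit` = 5 m·s⁻¹;
wheel speed integrates Newton's law against rolling resistance (explicit
Euler at the sample step, resistance active only while moving). The
force–velocity factor is the standard first-order sprint-biomechanics
description of effective force falling off with hand speed, and it is what
makes the design targets attainable across the strength range: a pure
amplitude-decay force model obeys the exact identity
`v_mean·μ·m·g = P30 − ½·m·v_end²/T`, which for strong participants forces
either a peak velocity above 3 m·s⁻¹ or a mean velocity more than 2% below
the 2.0 m·s⁻¹ design target. Wingate push amplitude decays linearly by
the participant's `fatigue_rate` (population N(0.60, 0.05), clipped to
[0.45, 0.70]); 0.60 was chosen from the same identity so that the terminal
kinetic energy keeps the extracted 30 s mean velocity within 2% of the
design target for mid-cohort capacities. Consequences worth knowing:
extracted rate of fatigue runs around 45–60%, somewhat above the reference
cohort's 38 ± 11%, and very weak participants (≲1.5 N·kg⁻¹) undershoot the
2.0 m·s⁻¹ velocity target by up to ~13% because their start-up transient
never fully decays — which is also why the real cohort averaged 1.9 m·s⁻¹.
Amplitudes are calibrated by bisection against the integrator (realized
windowed mean power within 0.5% of target; bracket doubling then 60
bisection steps); an unreachable Wingate target raises a calibration
error, an unreachable sprint target falls back to maximal effort.

Sprint capacity is 0.72·P30 (the reference cohort's sprint-to-Wingate
power ratio, 69 W vs 97 W). The GXT holds the prescribed velocity while
each stage's required power is strictly below endurance capacity
`po_peak·(1 + endurance_jitter)` (jitter N(0, 0.04) clipped to ±0.08,
zero in noise-free mode); at the first stage *reaching* capacity the
target power is held 3 s and velocity then decays to zero over 5 s. The
strict-inequality failure rule makes a capacity-equals-estimate
participant complete exactly stages 1–10 (stage 11 requires 100%) — a
participant cannot sustain for a whole minute the power defined as their
highest 30 s mean. Heart rate follows a first-order response (τ = 30 s)
toward `hr_rest + (hr_max − hr_rest)·P/capacity`, saturating at `hr_max`;
RPE ratings are discretized N(7, 1) central and N(9, 1) peripheral,
clipped to 1–10 (the novice pattern of peripheral-limited effort).

What the generator does *not* emulate: push-by-push biomechanics (contact
angles, cycle asymmetry), wheel slip and brake failure (hardware failures
appear only as missing tests), flywheel/inertia corrections (simulated
inertia equals total mass on the rollers), circadian or between-site
variation, and within-participant trial-to-trial variability beyond sensor
noise. Passing recovery tests therefore show that the *analysis chain* is
unbiased under the assumed linear structure — not that the structure holds
in any real population.

## Problem sizes and numerical choices

The parameter-recovery check simulates a 200-participant cohort through
all four tests (about ten seconds of compute); protocol-design checks use
a representative mid-cohort participant (75 kg user, 10 kg wheelchair,
2.9 N·kg⁻¹ strength, fatigue 0.6). Euler integration runs at the sample
step (10 ms); stage-power comparisons use a 1e-9 relative tolerance so
that exact capacity equality is classified as failure deterministically.
Display rounding is half-away-from-zero on the shortest decimal
representation of the double (so 0.95·179 = 170.04999… reports as 170).

## Known limitations

* The bundled cohort table holds printed (rounded) values; reconstructed
  regression coefficients can differ from the study's in the second
  decimal, and the two inferential p-values (0.418, 0.015) depend on
  unrounded raw data and are reported for inspection only.
* Wingate RF and sprint peak power in synthetic traces are plausible but
  not calibrated against the reference cohort's distributions.
* The submaximal propulsion-technique bouts, spirometry outcomes and the
  ergometer's internal friction calibration are out of scope.
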