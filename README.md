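# wheelergo

Analysis pipeline for **standardized, individualized wheelchair-specific
exercise-capacity testing** on a dual-roller ergometer — for exercise
physiologists, rehabilitation researchers and sports scientists who test
wheelchair users (or novices) with an isometric strength test, a 10 s
sprint, a 30 s Wingate test (WAnT) and a graded exercise test (GXT).

Resistance settings for maximal wheelchair tests are traditionally set by
tester experience, which makes protocols hard to reproduce or compare.
This package implements the alternative: scale every test from the
previous test's measured outcome.

## The model

Per-side wheel torque `M` and linear wheel velocity `v` (100 Hz) are
low-pass filtered (4th-order Butterworth, 10 Hz, zero-phase) and converted
to handrim force and power:

```
F  = M / r_r                    (N,   per side; outcomes use the L/R mean)
PO = (M / r_w) · v              (W,   per side; outcomes use the L/R sum)
```

The test chain is scaled by two per-kg regressions and a power balance:

```
P30_est    = 0.51 · F_iso − 0.18          (W·kg⁻¹ from N·kg⁻¹)
μ_WAnT     = P30_est / (2.0 · m_total · g)        (targets v̄ = 2 m·s⁻¹)
POpeak_est = 0.67 · P30_meas + 0.11       (W·kg⁻¹)
GXT stage n: (0.20 + 0.08·(n−1)) · POpeak_est at 1.39 m·s⁻¹, 1 min/stage
```

Outcomes: `F_iso` (best 3 s rolling-mean force), sprint mean/peak power
and velocity, WAnT `P30`/`P5`/`RF`, GXT `POpeak` (highest 30 s rolling
mean), duration, `HR_peak` and overall RPE. Validity: WAnT peak velocity
≤ 3 m·s⁻¹; GXT duration 8–12 min (primary), HR ≥ 95% of (200 − age) and
RPE ≥ 8 (secondary). Cohort statistics compare estimates with
measurements (±20% boundaries, Wilcoxon/paired-t gated by Shapiro-Wilk)
and reconstruct the scaling equations with Theil-Sen regression. A
synthetic generator produces seeded, bit-reproducible 100 Hz traces for
all four tests with the same latent linear structure, so the entire chain
is testable without an ergometer. See `docs/methods.md` for assumptions
and numerical choices.

## Worked example

Scale a Wingate and a GXT for a 72 kg participant in a 10 kg wheelchair
(0.34 m wheels, 0.31 m rims) whose isometric strength was 214 N and whose
measured Wingate power was 97 W:

```python
>>> import wheelergo as w
>>> setup = w.WheelchairSetup(wheelchair_mass=10.0, wheel_radius=0.34,
...                           rim_radius=0.31, user_mass=72.0)
>>> _, p30_est = w.estimate_p30(214.0, 72.0)
>>> rx = w.wingate_resistance(p30_est, setup)
>>> round(p30_est, 1), round(rx.mu, 4)
(96.2, 0.0598)
>>> _, popeak_est = w.estimate_popeak(97.0, 72.0)
>>> sch = w.gxt_schedule(popeak_est, setup)
>>> round(popeak_est, 1), round(sch.stage_powers[0], 1), round(sch.stage_mus[0], 4)
(72.9, 14.6, 0.013)
```

So the Wingate runs at μ = 0.0598 (the resistance at which 96.2 W
sustained for 30 s averages 2 m·s⁻¹), and the graded test starts at
14.6 W (20% of the 72.9 W estimate), climbing 5.8 W per minute to reach
100% at minute 11.

The bundled 20-participant study table drives the cohort analysis:

```python
>>> t = w.load_table1()
>>> s = w.cohort_summary(t)
>>> s.loc["mean", "f_iso_N"], s.loc["mean", "p30_meas_W"], s.loc["mean", "popeak_meas_W"]
(214.0, 97.0, 61.0)
>>> sub = t.dropna(subset=["popeak_est_W"])
>>> c = w.compare_estimates(sub["popeak_est_W"], sub["popeak_meas_W"])
>>> round(c.mean_deviation, 1), round(c.sd_deviation, 1), c.test_used, round(c.p_value, 3)
(-10.1, 16.6, 't', 0.015)
```

i.e. on this cohort the GXT estimate overshot the measured peak power by
10.1 ± 16.6% (paired t-test p = 0.015) — the aerobic test scales less
accurately than the Wingate, whose deviation is −1.5 ± 11.3% (Wilcoxon
p = 0.443). `wheelergo report` prints the same summary from the shell,
together with validity counts (1/20 invalid Wingates, 6/17 invalid GXT
durations) and the Theil-Sen reconstruction (per-kg P30 on F_iso: slope
0.44, R² 0.84, n = 19).

Command line: `wheelergo simulate` (synthetic cohort of trace files),
`wheelergo analyze` (trace directory → outcome table), `wheelergo scale`
(one outcome → next prescription), `wheelergo report`, and
`wheelergo fixtures table1`.

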