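"""Synthetic participants and 100 Hz ergometer traces for all four tests.

The generator exists so that every pipeline stage — filtering, outcome
extraction, protocol scaling, validity, cohort regression — is testable
end-to-end without instrument data.  It embeds the same linear structure
the scaling equations assume: each participant carries latent per-kg
capacities

* ``p30_per_kg = 0.51 · f_iso_per_kg − 0.18 + ε₁``, ``ε₁ ~ N(0, σ₁)``
* ``po_peak_per_kg = 0.67 · p30_per_kg + 0.11 + ε₂``, ``ε₂ ~ N(0, σ₂)``

(rejection-resampled to stay positive), with population moments matching
the reference cohort (body mass 72 ± 11 kg, age 23 ± 2 y, isometric
strength 2.9 ± 0.8 N·kg⁻¹).

Trace synthesis
---------------
Pushing is modelled as a half-rectified sinusoidal drive force at the
participant's push frequency, scaled by a linear force–velocity factor
``max(0, 1 − v/v_limit)`` (effective force falls off as hand speed rises —
the same coordination limit that motivates the 3 m·s⁻¹ validity cap).
Wheel speed integrates ``m_total · dv/dt = F_drive − μ · m_total · g``
(rolling resistance acts only while moving).  For the Wingate the push
amplitude additionally decays linearly by ``fatigue_rate`` over the 30 s.
The force amplitude is calibrated by bisection so the realized windowed
mean power meets the requested target (0.5% tolerance), because the
start-up transient makes the mean non-analytic.

The graded test holds velocity at the prescribed 1.39 m·s⁻¹; a stage is
sustainable while its required power is strictly below the participant's
endurance capacity ``po_peak · (1 + endurance_jitter)``; at the first stage
reaching capacity the effort collapses and velocity decays to zero within
a few seconds.  Heart rate follows a first-order response (τ = 30 s) from
rest toward a target set by the current relative load, saturating at the
participant's maximum.

Identical seed and configuration produce bit-identical traces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import CalibrationError, InvalidConfigurationError
from .metrics import (
    gxt_outcomes,
    isometric_strength,
    sprint_outcomes,
    wingate_outcomes,
)
from .scaling import (
    GXTSchedule,
    WAnTPrescription,
    estimate_p30,
    estimate_popeak,
    gxt_schedule,
    wingate_resistance,
)
from .signals import (
    GRAVITY,
    ErgometerTrace,
    WheelchairSetup,
    compute_force_power,
    filter_trace,
)
from .validity import validate_gxt, validate_wingate

__all__ = [
    "SimulationConfig", "ParticipantModel", "SimulatedGXT",
    "generate_cohort", "simulate_isometric", "simulate_sprint",
    "simulate_wingate", "simulate_gxt",
    "run_simulated_protocol", "simulate_cohort_table",
]

# latent-structure coefficients (kept equal to the scaling equations)
_P30_SLOPE, _P30_ICEPT = 0.51, -0.18
_POPEAK_SLOPE, _POPEAK_ICEPT = 0.67, 0.11


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions and noise levels of the synthetic cohort.

    Defaults reproduce the reference study's conditions: 100 Hz sampling,
    a 10 kg wheelchair with 0.34 m wheels and 0.31 m handrims, gym-court
    sprint resistance μ = 0.012, a 2.0 m·s⁻¹ Wingate design velocity and a
    1.39 m·s⁻¹ graded-test velocity.
    """

    seed: int = 0
    rate: float = 100.0
    # wheelchair geometry (reference tennis wheelchair)
    chair_mass: float = 10.0
    wheel_radius: float = 0.34
    rim_radius: float = 0.31
    # sensor noise
    torque_noise_sd: float = 0.2       # N·m per side
    velocity_noise_sd: float = 0.01    # m·s⁻¹ per side
    # latent-structure noise (per-kg)
    sigma1: float = 0.05               # W·kg⁻¹, P30 | F_iso
    sigma2: float = 0.05               # W·kg⁻¹, POpeak | P30
    endurance_jitter_sd: float = 0.04  # day-to-day fraction of capacity
    # protocol parameters
    sprint_mu: float = 0.012
    sprint_duration: float = 10.0
    sprint_ratio: float = 0.72         # sprint PO_mean as a fraction of P30
    want_target_v: float = 2.0
    want_duration: float = 30.0
    gxt_velocity: float = 1.39
    gxt_n_stages: int = 15
    # effort model
    hand_speed_limit: float = 5.0      # m·s⁻¹, force-velocity fall-off scale
    iso_rise_tau: float = 0.3          # s, isometric force rise constant
    hr_tau: float = 30.0               # s, heart-rate response constant
    lead_in: float = 1.0               # s of idle signal before test_start

    def noise_free(self) -> "SimulationConfig":
        """Copy with every stochastic influence on the traces removed."""
        return dataclasses.replace(
            self, torque_noise_sd=0.0, velocity_noise_sd=0.0,
            sigma1=0.0, sigma2=0.0, endurance_jitter_sd=0.0,
        )

    def setup_for(self, participant: "ParticipantModel") -> WheelchairSetup:
        return WheelchairSetup(
            wheelchair_mass=self.chair_mass,
            wheel_radius=self.wheel_radius,
            rim_radius=self.rim_radius,
            user_mass=participant.body_mass,
        )


@dataclass(frozen=True)
class ParticipantModel:
    """Latent description of one synthetic participant."""

    id: int
    sex: str
    age: float                  # y
    body_mass: float            # kg
    f_iso_per_kg: float         # N·kg⁻¹, latent isometric strength
    p30_per_kg: float           # W·kg⁻¹, latent 30 s anaerobic power
    po_peak_per_kg: float       # W·kg⁻¹, latent peak aerobic power
    hr_rest: float              # bpm
    hr_max: float               # bpm
    push_frequency: float       # Hz
    fatigue_rate: float         # push-amplitude fraction lost over 30 s
    endurance_jitter: float     # day-to-day fractional capacity shift

    @property
    def f_iso(self) -> float:
        return self.f_iso_per_kg * self.body_mass

    @property
    def p30(self) -> float:
        return self.p30_per_kg * self.body_mass

    @property
    def po_peak(self) -> float:
        return self.po_peak_per_kg * self.body_mass


@dataclass(frozen=True)
class SimulatedGXT:
    """A simulated graded test plus the post-test exertion ratings."""

    trace: ErgometerTrace
    rpe_central: int
    rpe_peripheral: int
    exhausted: bool             # False when the schedule ran out first
    completed_stages: int


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def generate_cohort(n: int, config: SimulationConfig) -> list[ParticipantModel]:
    """Draw ``n`` participants from the population model (seeded)."""
    if n < 1:
        raise InvalidConfigurationError("cohort size must be >= 1")
    rng = _rng(config, 0)
    out = []
    for i in range(n):
        sex = "F" if rng.random() < 0.5 else "M"
        age = float(np.clip(np.round(rng.normal(23.0, 2.0)), 18, 30))
        mass = float(np.clip(rng.normal(72.0, 11.0), 45.0, 110.0))
        # rejection-resample the latent chain until every capacity is positive
        for _ in range(1000):
            f_iso_kg = float(np.clip(rng.normal(2.9, 0.8), 0.8, 5.0))
            p30_kg = _P30_SLOPE * f_iso_kg + _P30_ICEPT + rng.normal(0.0, config.sigma1)
            po_kg = _POPEAK_SLOPE * p30_kg + _POPEAK_ICEPT + rng.normal(0.0, config.sigma2)
            if p30_kg > 0.05 and po_kg > 0.05:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise CalibrationError("could not draw positive latent capacities")
        jitter = 0.0
        if config.endurance_jitter_sd > 0:
            jitter = float(np.clip(rng.normal(0.0, config.endurance_jitter_sd),
                                   -0.08, 0.08))
        out.append(ParticipantModel(
            id=i + 1,
            sex=sex,
            age=age,
            body_mass=mass,
            f_iso_per_kg=f_iso_kg,
            p30_per_kg=float(p30_kg),
            po_peak_per_kg=float(po_kg),
            hr_rest=float(np.clip(rng.normal(65.0, 8.0), 45.0, 90.0)),
            hr_max=float(200.0 - age),
            push_frequency=float(np.clip(rng.normal(1.5, 0.15), 1.0, 2.0)),
            fatigue_rate=float(np.clip(rng.normal(0.60, 0.05), 0.45, 0.70)),
            endurance_jitter=jitter,
        ))
    return out


# ---------------------------------------------------------------------------
# trace assembly helpers

def _assemble_trace(config: SimulationConfig, time: np.ndarray,
                    torque_side: np.ndarray, velocity: np.ndarray,
                    rng: Optional[np.random.Generator],
                    heart_rate: Optional[np.ndarray] = None,
                    test_start: float = 0.0) -> ErgometerTrace:
    """Duplicate the per-side channels, add sensor noise, build the trace."""
    tl = torque_side.copy()
    tr = torque_side.copy()
    vl = velocity.copy()
    vr = velocity.copy()
    if rng is not None and config.torque_noise_sd > 0:
        tl += rng.normal(0.0, config.torque_noise_sd, tl.size)
        tr += rng.normal(0.0, config.torque_noise_sd, tr.size)
    if rng is not None and config.velocity_noise_sd > 0:
        vl = np.clip(vl + rng.normal(0.0, config.velocity_noise_sd, vl.size), 0, None)
        vr = np.clip(vr + rng.normal(0.0, config.velocity_noise_sd, vr.size), 0, None)
    return ErgometerTrace(
        time=time, torque_left=tl, torque_right=tr,
        velocity_left=vl, velocity_right=vr,
        rate=config.rate, heart_rate=heart_rate, test_start=test_start,
    )


def simulate_isometric(p: ParticipantModel, config: SimulationConfig,
                       trial: int = 0, duration: float = 5.0) -> ErgometerTrace:
    """One 5 s maximal isometric trial (wheels blocked, velocity zero).

    Each arm's handrim force rises with a first-order response (τ = 0.3 s)
    to a plateau equal to the participant's latent F_iso, so the
    side-averaged force analysed downstream plateaus at the latent value.
    """
    rng = _rng(config, p.id, 1, trial)
    dt = 1.0 / config.rate
    n_lead = int(round(config.lead_in * config.rate))
    n_test = int(round(duration * config.rate))
    t = np.arange(n_lead + n_test) * dt
    force_side = np.zeros(t.size)
    tt = (np.arange(n_test) + 1) * dt
    force_side[n_lead:] = p.f_iso * (1.0 - np.exp(-tt / config.iso_rise_tau))
    torque_side = force_side * config.rim_radius
    velocity = np.zeros(t.size)
    noise_rng = rng if config.torque_noise_sd > 0 or config.velocity_noise_sd > 0 else None
    return _assemble_trace(config, t, torque_side, velocity, noise_rng,
                           test_start=config.lead_in)


def _integrate_effort(base: np.ndarray, amplitude: float, mu: float,
                      m_total: float, v_limit: float, dt: float,
                      g: float = GRAVITY) -> tuple[np.ndarray, np.ndarray]:
    """Integrate wheel speed under pushing and rolling resistance.

    ``base`` is the unscaled drive-force waveform (ground frame, both arms
    summed); the applied force is ``amplitude · base · max(0, 1 − v/v_limit)``.
    Rolling resistance ``μ·m·g`` acts only while the wheels turn; a push too
    weak to overcome it from standstill leaves the chair parked.
    Returns ``(velocity, applied_drive_force)`` sampled on the same grid.
    """
    n = base.size
    v = np.empty(n)
    drive = np.empty(n)
    resist = mu * m_total * g
    vk = 0.0
    for k in range(n):
        f = amplitude * base[k] * (1.0 - vk / v_limit)
        if f < 0.0:
            f = 0.0
        drive[k] = f
        if vk <= 0.0 and f <= resist:
            a = 0.0
            vk = 0.0
        else:
            a = (f - resist) / m_total
            vk += a * dt
            if vk < 0.0:
                vk = 0.0
        v[k] = vk
    return v, drive


def _calibrate_amplitude(base: np.ndarray, window: slice, target: float,
                         mu: float, m_total: float, v_limit: float, dt: float,
                         rel_tol: float = 5e-3, on_fail: str = "raise"
                         ) -> tuple[float, np.ndarray, np.ndarray]:
    """Bisect the push amplitude so mean delivered power hits ``target``.

    Delivered power is ``drive · v`` averaged over ``window``.  Returns
    ``(amplitude, velocity, drive)``.  If even a very large amplitude
    cannot reach the target (the force-velocity limit caps deliverable
    power), either raise :class:`CalibrationError` or, with
    ``on_fail='max'``, return the best-effort maximal push.
    """
    def realized(a: float):
        v, drive = _integrate_effort(base, a, mu, m_total, v_limit, dt)
        return float(np.mean(drive[window] * v[window])), v, drive

    lo, hi = 0.0, 200.0
    p_hi, v_hi, d_hi = realized(hi)
    for _ in range(20):
        if p_hi >= target:
            break
        lo, hi = hi, hi * 2.0
        p_hi, v_hi, d_hi = realized(hi)
    else:
        if on_fail == "max":
            return hi, v_hi, d_hi
        raise CalibrationError(
            f"target mean power {target:.1f} W unreachable "
            f"(max ≈ {p_hi:.1f} W at this resistance)"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        p_mid, v_mid, d_mid = realized(mid)
        if abs(p_mid - target) <= rel_tol * target:
            return mid, v_mid, d_mid
        if p_mid < target:
            lo = mid
        else:
            hi = mid
    return mid, v_mid, d_mid  # pragma: no cover - bisection always converges


def _push_base(config: SimulationConfig, p: ParticipantModel, duration: float,
               fatigue_rate: float = 0.0) -> tuple[np.ndarray, np.ndarray, slice]:
    """Time grid, unscaled drive waveform and the analysis window slice."""
    dt = 1.0 / config.rate
    n_lead = int(round(config.lead_in * config.rate))
    n_test = int(round(duration * config.rate))
    t = np.arange(n_lead + n_test) * dt
    base = np.zeros(t.size)
    tt = np.arange(n_test) * dt
    wave = np.maximum(0.0, np.sin(2.0 * np.pi * p.push_frequency * tt))
    decay = 1.0 - fatigue_rate * tt / duration if fatigue_rate > 0 else 1.0
    base[n_lead:] = wave * decay
    return t, base, slice(n_lead, n_lead + n_test)


def _dynamic_trace(config: SimulationConfig, p: ParticipantModel,
                   t: np.ndarray, v: np.ndarray, drive: np.ndarray,
                   rng: Optional[np.random.Generator]) -> ErgometerTrace:
    # summed ground drive force -> per-side wheel torque via the wheel radius
    torque_side = 0.5 * drive * config.wheel_radius
    return _assemble_trace(config, t, torque_side, v, rng,
                           test_start=config.lead_in)


def simulate_sprint(p: ParticipantModel, config: SimulationConfig,
                    trial: int = 0, duration: Optional[float] = None,
                    mu: Optional[float] = None) -> ErgometerTrace:
    """One 10 s all-out sprint from standstill at gym-court resistance.

    The push amplitude is calibrated so the 10 s mean summed power
    approximates the participant's sprint capacity — a fixed fraction
    (``config.sprint_ratio``, default 0.72) of the latent P30, matching the
    reference cohort's sprint-to-Wingate power ratio.  If the
    force-velocity limit caps power below that target the sprint proceeds
    at maximal effort instead.
    """
    duration = config.sprint_duration if duration is None else duration
    mu = config.sprint_mu if mu is None else mu
    rng = _rng(config, p.id, 2, trial)
    setup = config.setup_for(p)
    t, base, window = _push_base(config, p, duration)
    target = config.sprint_ratio * p.p30
    _, v, drive = _calibrate_amplitude(
        base, window, target, mu, setup.total_mass,
        config.hand_speed_limit, 1.0 / config.rate, on_fail="max",
    )
    noise_rng = rng if config.torque_noise_sd > 0 or config.velocity_noise_sd > 0 else None
    return _dynamic_trace(config, p, t, v, drive, noise_rng)


def simulate_wingate(p: ParticipantModel, prescription: WAnTPrescription,
                     config: SimulationConfig,
                     realized_p30: Optional[float] = None) -> ErgometerTrace:
    """A 30 s Wingate at the prescribed resistance, from standstill.

    The push amplitude decays linearly by ``p.fatigue_rate`` over the test
    and is calibrated by bisection so the realized 30 s mean summed power
    equals the participant's latent P30 (or ``realized_p30`` if given)
    within 0.5%.

    Raises
    ------
    CalibrationError
        If the prescribed resistance makes the target power unreachable.
    """
    if prescription.mu <= 0:
        raise InvalidConfigurationError("prescribed mu must be positive")
    rng = _rng(config, p.id, 3)
    setup = config.setup_for(p)
    t, base, window = _push_base(config, p, config.want_duration,
                                 fatigue_rate=p.fatigue_rate)
    target = p.p30 if realized_p30 is None else realized_p30
    _, v, drive = _calibrate_amplitude(
        base, window, target, prescription.mu, setup.total_mass,
        config.hand_speed_limit, 1.0 / config.rate, on_fail="raise",
    )
    noise_rng = rng if config.torque_noise_sd > 0 or config.velocity_noise_sd > 0 else None
    return _dynamic_trace(config, p, t, v, drive, noise_rng)


def simulate_gxt(p: ParticipantModel, schedule: GXTSchedule,
                 config: SimulationConfig,
                 capacity: Optional[float] = None) -> SimulatedGXT:
    """Graded test to exhaustion at constant velocity.

    The participant sustains every minute-stage whose required power is
    strictly below their endurance capacity (``po_peak · (1 +
    endurance_jitter)`` unless ``capacity`` is given); at the first stage
    reaching capacity the effort collapses: the target power is held for
    3 s, then velocity decays to zero over 5 s and the recording stops.
    """
    rng = _rng(config, p.id, 4)
    dt = 1.0 / config.rate
    cap = p.po_peak * (1.0 + p.endurance_jitter) if capacity is None else capacity
    v_cruise = schedule.constant_velocity

    segments = []       # (n_samples, power W, velocity profile factor)
    completed = 0
    exhausted = False
    for i in range(1, schedule.n_stages + 1):
        req = schedule.stage_power(i)
        if req < cap * (1.0 - 1e-9):
            segments.append(("hold", int(round(60.0 * config.rate)), req))
            completed += 1
        else:
            exhausted = True
            segments.append(("hold", int(round(3.0 * config.rate)), req))
            segments.append(("decay", int(round(5.0 * config.rate)), req))
            break

    n_lead = int(round(config.lead_in * config.rate))
    n_total = n_lead + sum(n for _, n, _ in segments)
    t = np.arange(n_total) * dt
    power_target = np.zeros(n_total)   # cycle-mean summed power, W
    velocity = np.zeros(n_total)
    hr = np.empty(n_total)

    # push waveform with continuous phase over the whole test
    wave = np.pi * np.maximum(0.0, np.sin(2.0 * np.pi * p.push_frequency
                                          * (t - config.lead_in)))
    hr_now = p.hr_rest
    hr[:n_lead] = p.hr_rest
    k = n_lead
    for kind, n, req in segments:
        idx = slice(k, k + n)
        tt = (np.arange(n) + 1) * dt
        if kind == "hold":
            velocity[idx] = v_cruise
            power_target[idx] = req
        else:
            s = np.clip(1.0 - tt / (n * dt), 0.0, None)
            velocity[idx] = v_cruise * s
            power_target[idx] = req * s**2
        # heart rate: first-order approach to the load-dependent target
        target_hr = p.hr_rest + (p.hr_max - p.hr_rest) * min(1.0, req / max(cap, 1e-9))
        hr[idx] = target_hr + (hr_now - target_hr) * np.exp(-tt / config.hr_tau)
        hr_now = float(hr[k + n - 1])
        k += n

    power = power_target * wave
    with np.errstate(divide="ignore", invalid="ignore"):
        drive = np.where(velocity > 1e-6, power / np.where(velocity > 1e-6,
                                                           velocity, 1.0), 0.0)
    torque_side = 0.5 * drive * config.wheel_radius
    noise_rng = rng if config.torque_noise_sd > 0 or config.velocity_noise_sd > 0 else None
    trace = _assemble_trace(config, t, torque_side, velocity, noise_rng,
                            heart_rate=hr, test_start=config.lead_in)
    rpe_c = int(np.clip(np.round(rng.normal(7.0, 1.0)), 1, 10))
    rpe_p = int(np.clip(np.round(rng.normal(9.0, 1.0)), 1, 10))
    return SimulatedGXT(trace=trace, rpe_central=rpe_c, rpe_peripheral=rpe_p,
                        exhausted=exhausted, completed_stages=completed)


# ---------------------------------------------------------------------------
# full-protocol driver

def _analyze(trace: ErgometerTrace, setup: WheelchairSetup):
    return compute_force_power(filter_trace(trace), setup)


def run_simulated_protocol(p: ParticipantModel, config: SimulationConfig) -> dict:
    """Simulate and analyse the full test chain for one participant.

    Runs isometric → sprint → Wingate → GXT with each resistance prescribed
    from the preceding result, exactly as the analysis pipeline would on
    instrument data, and returns one cohort-table row (plus the latent
    ground truth under ``true_*`` keys).
    """
    setup = config.setup_for(p)
    row: dict = {
        "id": p.id, "sex": p.sex, "age_y": p.age, "body_mass_kg": p.body_mass,
        "true_f_iso_N_per_kg": p.f_iso_per_kg,
        "true_p30_W_per_kg": p.p30_per_kg,
        "true_popeak_W_per_kg": p.po_peak_per_kg,
    }

    iso_trials = [_analyze(simulate_isometric(p, config, trial=i), setup)
                  for i in range(3)]
    iso = isometric_strength(iso_trials, p.body_mass)
    row["f_iso_N"] = iso.f_iso
    row["f_iso_N_per_kg"] = iso.f_iso_per_kg

    sprints = [_analyze(simulate_sprint(p, config, trial=i), setup)
               for i in range(2)]
    sprint = sprint_outcomes(sprints, config.sprint_duration)
    row.update({
        "sprint_po_mean_W": sprint.po_mean, "sprint_po_max_W": sprint.po_max,
        "sprint_v_mean_ms": sprint.v_mean, "sprint_v_max_ms": sprint.v_max,
        "sprint_po_mean_W_per_kg": sprint.po_mean / p.body_mass,
        "sprint_po_max_W_per_kg": sprint.po_max / p.body_mass,
    })

    _, p30_est = estimate_p30(iso.f_iso, p.body_mass)
    prescription = wingate_resistance(p30_est, setup, config.want_target_v)
    want = wingate_outcomes(
        _analyze(simulate_wingate(p, prescription, config), setup),
        config.want_duration,
    )
    row.update({
        "p30_est_W": p30_est, "p30_meas_W": want.p30,
        "p30_meas_W_per_kg": want.p30 / p.body_mass,
        "want_p5_W": want.p5, "want_po_max_W": want.po_max,
        "want_rf_pct": want.rf, "want_v_mean_ms": want.v_mean,
        "want_v_max_ms": want.v_max, "want_mu": prescription.mu,
        "want_valid": validate_wingate(want).valid,
    })

    _, popeak_est = estimate_popeak(want.p30, p.body_mass)
    schedule = gxt_schedule(popeak_est, setup, config.gxt_n_stages,
                            config.gxt_velocity)
    sim_gxt = simulate_gxt(p, schedule, config)
    gxt = gxt_outcomes(_analyze(sim_gxt.trace, setup),
                       sim_gxt.rpe_central, sim_gxt.rpe_peripheral)
    report = validate_gxt(gxt, p.age)
    row.update({
        "popeak_est_W": popeak_est, "popeak_meas_W": gxt.po_peak,
        "popeak_meas_W_per_kg": gxt.po_peak / p.body_mass,
        "gxt_duration_s": gxt.duration, "hr_peak_bpm": gxt.hr_peak,
        "rpe_central": gxt.rpe_central, "rpe_peripheral": gxt.rpe_peripheral,
        "rpe_overall": gxt.rpe_overall,
        "gxt_completed_stages": gxt.completed_stages,
        "gxt_duration_valid": report.gxt_duration_valid,
        "gxt_hr_valid": report.gxt_hr_valid,
        "gxt_rpe_valid": report.gxt_rpe_valid,
    })
    return row


def simulate_cohort_table(n: int, config: SimulationConfig,
                          participants: Optional[Sequence[ParticipantModel]] = None):
    """Full-protocol cohort table for ``n`` generated participants."""
    import pandas as pd

    if participants is None:
        participants = generate_cohort(n, config)
    rows = [run_simulated_protocol(p, config) for p in participants]
    return pd.DataFrame(rows)
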