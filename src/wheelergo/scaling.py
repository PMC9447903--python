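"""Individualized resistance prescriptions chained from test outcomes.

The protocol scales each test from the previous one through two empirical
regressions (established in wheelchair users with a spinal cord injury) and
a power balance:

* ``P30_est [W·kg⁻¹] = 0.51 · F_iso [N·kg⁻¹] − 0.18`` — isometric strength
  predicts 30 s anaerobic power; the absolute estimate multiplies by body
  mass.
* ``μ = P30_est / (v_target · m_total · g)`` — the Wingate rolling
  resistance that should make the participant average ``v_target`` (2.0
  m·s⁻¹, safely below the 3 m·s⁻¹ coordination limit).  ``m_total · g`` is
  the combined user + wheelchair weight.
* ``POpeak_est [W·kg⁻¹] = 0.67 · P30_meas [W·kg⁻¹] + 0.11`` — measured
  Wingate power predicts peak aerobic power.
* GXT stage schedule at a constant 1.39 m·s⁻¹: stage *n* (one minute each)
  requires ``(0.20 + 0.08·(n−1)) · POpeak_est``, i.e. a 20% start and
  constant increments of 8% (10% of the gap between the start load and
  POpeak_est), reaching 100% in stage 11 so that exhaustion lands around
  minute 10.

Estimates stay at full precision internally; the ``*_report`` helpers round
half-up to whole watts the way the printed cohort table does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._round import round_half_up
from .errors import InvalidConfigurationError, NoResultError
from .signals import WheelchairSetup

__all__ = [
    "P30_SLOPE", "P30_INTERCEPT", "POPEAK_SLOPE", "POPEAK_INTERCEPT",
    "WANT_TARGET_VELOCITY", "GXT_VELOCITY",
    "WAnTPrescription", "GXTSchedule",
    "estimate_p30", "wingate_resistance", "estimate_popeak", "gxt_schedule",
]

# per-kg regression coefficients (reference-cohort equations)
P30_SLOPE = 0.51
P30_INTERCEPT = -0.18
POPEAK_SLOPE = 0.67
POPEAK_INTERCEPT = 0.11

WANT_TARGET_VELOCITY = 2.0   # m·s⁻¹, design mean velocity of the Wingate
GXT_VELOCITY = 1.39          # m·s⁻¹, constant velocity of the graded test
GXT_START_FRACTION = 0.20    # stage 1 load as a fraction of POpeak_est
GXT_INCREMENT_FRACTION = 0.08  # per-minute increment fraction


@dataclass(frozen=True)
class WAnTPrescription:
    """Individualized Wingate resistance setting."""

    p30_est: float            # W
    p30_est_per_kg: float     # W·kg⁻¹
    target_v_mean: float      # m·s⁻¹
    mu: float                 # dimensionless rolling-resistance coefficient


@dataclass(frozen=True)
class GXTSchedule:
    """Minute-stage schedule of the graded exercise test."""

    po_peak_est: float        # W
    stage_powers: tuple       # W per stage, stage 1 first
    stage_mus: tuple          # per-stage resistance coefficients
    constant_velocity: float  # m·s⁻¹

    @property
    def n_stages(self) -> int:
        return len(self.stage_powers)

    def stage_power(self, stage: int) -> float:
        """Required power of 1-based ``stage``, W."""
        return self.stage_powers[stage - 1]


def estimate_p30(f_iso: float, user_mass: float) -> tuple[float, float]:
    """Estimate 30 s Wingate power from isometric strength.

    Returns ``(per_kg, absolute)`` in (W·kg⁻¹, W).  A non-positive estimate
    is returned as-is (the caller decides whether a prescription is
    possible); it arises only for strength below 0.18/0.51 ≈ 0.35 N·kg⁻¹.
    """
    if user_mass <= 0:
        raise InvalidConfigurationError("user mass must be positive")
    if f_iso <= 0:
        raise InvalidConfigurationError("isometric strength must be positive")
    per_kg = P30_SLOPE * (f_iso / user_mass) + P30_INTERCEPT
    return per_kg, per_kg * user_mass


def wingate_resistance(p30_est: float, setup: WheelchairSetup,
                       target_v: float = WANT_TARGET_VELOCITY) -> WAnTPrescription:
    """Rolling-resistance coefficient that targets ``target_v`` mean velocity.

    ``μ = P30_est / (target_v · total weight)``; dividing the propulsive
    force P30_est/target_v by the total weight yields the dimensionless
    coefficient the ergometer expects.

    Raises
    ------
    NoResultError
        If ``p30_est`` is not positive — no resistance can be prescribed
        (mirrors the hardware-failure participant for whom strength could
        not be measured).
    """
    if target_v <= 0:
        raise InvalidConfigurationError("target velocity must be positive")
    if p30_est <= 0:
        raise NoResultError(
            f"cannot prescribe a Wingate resistance from P30_est={p30_est} W"
        )
    mu = p30_est / (target_v * setup.total_weight)
    return WAnTPrescription(
        p30_est=p30_est,
        p30_est_per_kg=p30_est / setup.user_mass,
        target_v_mean=target_v,
        mu=mu,
    )


def estimate_popeak(p30_meas: float, user_mass: float) -> tuple[float, float]:
    """Estimate GXT peak power from the measured Wingate P30.

    Returns ``(per_kg, absolute)`` in (W·kg⁻¹, W).
    """
    if user_mass <= 0:
        raise InvalidConfigurationError("user mass must be positive")
    if p30_meas < 0:
        raise InvalidConfigurationError("measured P30 cannot be negative")
    per_kg = POPEAK_SLOPE * (p30_meas / user_mass) + POPEAK_INTERCEPT
    return per_kg, per_kg * user_mass


def gxt_schedule(po_peak_est: float, setup: WheelchairSetup,
                 n_stages: int = 15, velocity: float = GXT_VELOCITY
                 ) -> GXTSchedule:
    """Minute-stage powers and resistance coefficients for the graded test.

    Stage *n* requires ``(0.20 + 0.08·(n−1)) · po_peak_est``; the per-stage
    μ follows from the constant-velocity power balance
    ``P = μ · m_total · g · v``.  ``n_stages`` defaults beyond stage 11
    (100%) so over-performing participants remain representable.
    """
    if po_peak_est <= 0:
        raise NoResultError(
            f"cannot build a stage schedule from POpeak_est={po_peak_est} W"
        )
    if n_stages < 1:
        raise InvalidConfigurationError("need at least one stage")
    n = np.arange(1, n_stages + 1)
    powers = po_peak_est * (GXT_START_FRACTION + GXT_INCREMENT_FRACTION * (n - 1))
    mus = powers / (velocity * setup.total_weight)
    return GXTSchedule(
        po_peak_est=po_peak_est,
        stage_powers=tuple(float(p) for p in powers),
        stage_mus=tuple(float(m) for m in mus),
        constant_velocity=velocity,
    )


def report_watts(value: float) -> int:
    """Whole-watt display rounding (half-up), as printed in outcome tables."""
    return int(round_half_up(value))
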