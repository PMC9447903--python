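"""Validity criteria for the Wingate and graded exercise tests.

A Wingate is valid when the participant could accelerate against the
resistance and the one-sample peak velocity did not exceed 3 m·s⁻¹ (above
that, hand-rim coordination rather than power limits the outcome; 3.01
m·s⁻¹ is already invalid).

A GXT is valid — primary criterion — when its duration falls in the 8–12
minute band (480–720 s inclusive): shorter tests are confounded by local
muscle fatigue, longer ones by drift, discomfort and thermal strain.
Secondary criteria indicate whether a true maximal effort was approached:
peak heart rate at or above 95% of the age-predicted maximum (200 − age,
threshold rounded half-up to whole bpm) and an overall RPE of at least 8.
The stated criteria are "over 95%" and "over 8"; applied strictly to
unrounded values they contradict the reference cohort's own failure counts,
so the operational rules here are ≥ with display rounding, which reproduce
those counts exactly.  Secondary criteria never overturn the duration
verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._round import round_half_up
from .metrics import GXTResult, WAnTResult

__all__ = [
    "WANT_V_LIMIT",
    "GXT_DURATION_MIN", "GXT_DURATION_MAX",
    "WingateValidity", "ValidityReport",
    "validate_wingate", "validate_gxt", "hr_threshold",
]

WANT_V_LIMIT = 3.0        # m·s⁻¹, maximal allowed one-sample peak velocity
WANT_MIN_V_MEAN = 0.5     # m·s⁻¹, "could accelerate" floor (configurable)
GXT_DURATION_MIN = 480.0  # s (8 min, inclusive)
GXT_DURATION_MAX = 720.0  # s (12 min, inclusive)
HR_FRACTION = 0.95
RPE_MIN = 8


@dataclass(frozen=True)
class WingateValidity:
    valid: bool
    reason: str


@dataclass(frozen=True)
class ValidityReport:
    """Per-test validity verdicts for one participant's GXT.

    ``gxt_valid`` equals the duration criterion — duration is the primary
    criterion; heart rate and RPE are secondary and may be ``None``
    (unknown) when the channel or rating is missing.
    """

    gxt_duration_valid: bool
    gxt_hr_valid: Optional[bool]
    gxt_rpe_valid: Optional[bool]

    @property
    def gxt_valid(self) -> bool:
        return self.gxt_duration_valid


def validate_wingate(result: WAnTResult, v_limit: float = WANT_V_LIMIT,
                     min_v_mean: float = WANT_MIN_V_MEAN) -> WingateValidity:
    """Valid iff v_max ≤ 3 m·s⁻¹ and the participant accelerated."""
    if result.v_mean <= min_v_mean:
        return WingateValidity(
            False,
            f"mean velocity {result.v_mean:.2f} m/s: could not accelerate "
            f"against the resistance",
        )
    if result.v_max > v_limit:
        return WingateValidity(
            False,
            f"peak velocity {result.v_max:.2f} m/s exceeds {v_limit:g} m/s",
        )
    return WingateValidity(True, "peak velocity within limit")


def hr_threshold(age: float, fraction: float = HR_FRACTION) -> float:
    """95% of the age-predicted maximal heart rate, rounded to whole bpm."""
    return float(round_half_up(fraction * (200.0 - age)))


def validate_gxt(result: GXTResult, age: Optional[float] = None) -> ValidityReport:
    """Evaluate one GXT against the duration (primary) and HR/RPE criteria."""
    duration_valid = GXT_DURATION_MIN <= result.duration <= GXT_DURATION_MAX
    if result.hr_peak is None or age is None:
        hr_valid: Optional[bool] = None
    else:
        hr_valid = result.hr_peak >= hr_threshold(age)
    rpe_valid = None if result.rpe_overall is None else result.rpe_overall >= RPE_MIN
    return ValidityReport(
        gxt_duration_valid=bool(duration_valid),
        gxt_hr_valid=hr_valid,
        gxt_rpe_valid=rpe_valid,
    )
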