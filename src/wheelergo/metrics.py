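"""Per-test scalar outcomes extracted from force/power traces.

Four tests make up the protocol, in fixed order:

* **isometric strength** — best-of-trials highest 3 s rolling mean of the
  side-averaged handrim force (F_iso, N);
* **10 s sprint** — mean/peak power (side sum) and velocity (side average)
  over 10 s against a gym-court resistance (μ = 0.012);
* **30 s Wingate (WAnT)** — P30 (30 s mean power), P5 (highest of the six
  successive 5 s interval means), one-sample peak power, rate of fatigue
  RF = (first 5 s mean − last 5 s mean) / first · 100%;
* **graded exercise test (GXT)** — POpeak (highest 30 s rolling mean of the
  summed power), duration to termination, peak heart rate and perceived
  exertion (RPE, central/peripheral on a 1–10 scale, overall = their
  average rounded half-up).

All windows are anchored at the trace's ``test_start``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._round import round_half_up
from .errors import DegenerateTraceError, InsufficientDataError, NoResultError
from .signals import ForcePowerTrace, rolling_mean_max

__all__ = [
    "IsometricResult",
    "SprintResult",
    "WAnTResult",
    "GXTResult",
    "isometric_strength",
    "sprint_outcomes",
    "wingate_outcomes",
    "gxt_outcomes",
]


@dataclass(frozen=True)
class IsometricResult:
    """Best-of-trials maximal isometric handrim strength."""

    f_iso: float                 # N, best 3 s rolling mean across trials
    f_iso_per_kg: float          # N·kg⁻¹
    trial_values: tuple          # per usable trial, N
    n_trials: int                # number of usable trials


@dataclass(frozen=True)
class SprintResult:
    """Outcomes of the sprint with the highest one-sample peak velocity."""

    po_mean: float               # W, summed power averaged over 10 s
    po_max: float                # W, one-sample peak of summed power
    v_mean: float                # m·s⁻¹, side-averaged velocity over 10 s
    v_max: float                 # m·s⁻¹, one-sample peak
    sprint_index: int            # which sprint was selected


@dataclass(frozen=True)
class WAnTResult:
    """30 s Wingate outcomes (all powers are the sum of both arms)."""

    p30: float                   # W, mean over 30 s
    p5: float                    # W, highest 5 s interval mean
    po_max: float                # W, one-sample peak
    rf: float                    # %, rate of fatigue
    v_mean: float                # m·s⁻¹
    v_max: float                 # m·s⁻¹
    p5_intervals: tuple          # the six successive 5 s interval means, W


@dataclass(frozen=True)
class GXTResult:
    """Graded-exercise-test outcomes."""

    po_peak: float               # W, highest 30 s rolling mean of summed power
    duration: float              # s, test_start to termination
    hr_peak: Optional[float]     # bpm, one-sample peak (None without monitor)
    rpe_central: int
    rpe_peripheral: int
    rpe_overall: int             # round-half-up average of the two
    completed_stages: int        # floor(duration / 60), informational


def _usable_window(trace: ForcePowerTrace, seconds: float) -> Optional[ForcePowerTrace]:
    """Segment of ``seconds`` after test_start, or None if too short."""
    seg = trace.after_start()
    n = int(round(seconds * trace.rate))
    if seg.n_samples < n:
        return None
    return seg


def isometric_strength(trials: Sequence[ForcePowerTrace], user_mass: float,
                       window: float = 3.0) -> IsometricResult:
    """Best 3 s rolling-mean force across up to three 5 s maximal trials.

    Trials shorter than one window after ``test_start`` are flagged unusable
    and skipped; if none remain (the participant who pushed through the
    brakes, say) a :class:`NoResultError` is raised.
    """
    values = []
    for trial in trials:
        seg = trial.after_start()
        if seg.n_samples < int(round(window * trial.rate)):
            continue
        value, _ = rolling_mean_max(seg.force_mean, window, trial.rate)
        values.append(value)
    if not values:
        raise NoResultError("no usable isometric trial")
    f_iso = max(values)
    return IsometricResult(
        f_iso=f_iso,
        f_iso_per_kg=f_iso / user_mass,
        trial_values=tuple(values),
        n_trials=len(values),
    )


def _sprint_single(trace: ForcePowerTrace, duration: float) -> Optional[SprintResult]:
    seg10 = _usable_window(trace, duration)
    if seg10 is None:
        return None
    n = int(round(duration * trace.rate))
    po = seg10.power_total[:n]
    v = seg10.velocity_mean[:n]
    return SprintResult(
        po_mean=float(po.mean()),
        po_max=float(po.max()),
        v_mean=float(v.mean()),
        v_max=float(v.max()),
        sprint_index=-1,
    )


def sprint_outcomes(sprints: Sequence[ForcePowerTrace], duration: float = 10.0
                    ) -> SprintResult:
    """Outcomes of the sprint with the highest one-sample peak velocity.

    Each sprint is evaluated over ``[test_start, test_start + duration)``;
    sprints too short for a full window are skipped.
    """
    results = []
    for i, sprint in enumerate(sprints):
        r = _sprint_single(sprint, duration)
        if r is not None:
            results.append((i, r))
    if not results:
        raise InsufficientDataError("no sprint long enough for analysis")
    best_i, best = max(results, key=lambda ir: ir[1].v_max)
    return SprintResult(
        po_mean=best.po_mean, po_max=best.po_max,
        v_mean=best.v_mean, v_max=best.v_max, sprint_index=best_i,
    )


def wingate_outcomes(trace: ForcePowerTrace, duration: float = 30.0,
                     n_intervals: int = 6) -> WAnTResult:
    """P30, P5 intervals, peak power, rate of fatigue and velocities.

    The 30 s window starts at ``test_start``.  The six interval means use
    equal sample counts, so P30 equals their mean to round-off by
    construction.
    """
    seg = _usable_window(trace, duration)
    if seg is None:
        raise InsufficientDataError(
            f"trace has less than {duration} s after test_start"
        )
    per = int(round(duration * trace.rate / n_intervals))
    n = per * n_intervals
    po = seg.power_total[:n]
    v = seg.velocity_mean[:n]
    intervals = po.reshape(n_intervals, per).mean(axis=1)
    if intervals[0] <= 0:
        raise DegenerateTraceError(
            "first 5 s interval mean power is not positive; RF undefined"
        )
    rf = (intervals[0] - intervals[-1]) / intervals[0] * 100.0
    return WAnTResult(
        p30=float(po.mean()),
        p5=float(intervals.max()),
        po_max=float(po.max()),
        rf=float(rf),
        v_mean=float(v.mean()),
        v_max=float(v.max()),
        p5_intervals=tuple(float(x) for x in intervals),
    )


def overall_rpe(rpe_central: int, rpe_peripheral: int) -> int:
    """Overall RPE: the central/peripheral average, rounded half-up."""
    for r in (rpe_central, rpe_peripheral):
        if not (1 <= r <= 10):
            raise ValueError(f"RPE {r} outside the 1-10 scale")
    return int(round_half_up((rpe_central + rpe_peripheral) / 2.0))


def gxt_outcomes(trace: ForcePowerTrace, rpe_central: int, rpe_peripheral: int,
                 window: float = 30.0) -> GXTResult:
    """POpeak (highest 30 s rolling mean), duration, HR peak and RPE.

    The duration runs from ``test_start`` to the last recorded sample (the
    operator stops the recording when the target velocity can no longer be
    maintained).  A missing heart-rate channel degrades gracefully:
    ``hr_peak`` is ``None`` and validity evaluation reports it as unknown.
    """
    seg = trace.after_start()
    if seg.n_samples < int(round(window * trace.rate)):
        raise InsufficientDataError(
            f"trace has less than {window} s after test_start"
        )
    po_peak, _ = rolling_mean_max(seg.power_total, window, trace.rate)
    duration = float(seg.time[-1] - seg.time[0]) + 1.0 / trace.rate
    hr_peak = None if seg.heart_rate is None else float(np.nanmax(seg.heart_rate))
    return GXTResult(
        po_peak=float(po_peak),
        duration=duration,
        hr_peak=hr_peak,
        rpe_central=int(rpe_central),
        rpe_peripheral=int(rpe_peripheral),
        rpe_overall=overall_rpe(rpe_central, rpe_peripheral),
        completed_stages=int(math.floor(duration / 60.0)),
    )
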