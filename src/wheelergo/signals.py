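"""Raw dual-roller ergometer traces: containers, filtering, force/power.

The ergometer samples per-side wheel torque (N·m) and linear wheel velocity
(m·s⁻¹) at a fixed rate (100 Hz on the instrument this package targets).
Two algebraic relations turn those channels into the quantities every test
outcome is built from:

* handrim-effective force per side ``F = M / r_r`` (torque over rim radius),
* power output per side ``PO = (M / r_w) · v`` (rim-drive force times wheel
  velocity),

so that ``PO = F · (r_r / r_w) · v`` holds sample-wise as an identity.

Channels are low-pass filtered (4th-order Butterworth, 10 Hz cut-off)
before any metric is extracted.  Filtering is applied zero-phase
(forward–backward), because the headline outcomes are rolling-window means
whose *location* must not be biased by filter lag; the effective order is
thereby doubled, which is documented behaviour.  Heart rate is never
filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as _signal

from .errors import (
    InsufficientDataError,
    InvalidConfigurationError,
    TraceFormatError,
)

__all__ = [
    "GRAVITY",
    "WheelchairSetup",
    "ErgometerTrace",
    "ForcePowerTrace",
    "filter_trace",
    "compute_force_power",
    "rolling_mean_max",
    "detect_test_start",
]

#: Standard gravity, m·s⁻², used to convert total mass to total weight when
#: interpreting the dimensionless rolling-resistance coefficient μ.
GRAVITY = 9.81

_TIME_TOL = 1e-9  # allowed deviation of the sample step from 1/rate, s


@dataclass(frozen=True)
class WheelchairSetup:
    """Wheelchair + user geometry and mass, tying torque to physical units.

    Parameters
    ----------
    wheelchair_mass : float
        Mass of the wheelchair, kg.
    wheel_radius : float
        Wheel radius r_w, m (0.34 m for the reference tennis wheelchair).
    rim_radius : float
        Handrim radius r_r, m (0.31 m for the reference tennis wheelchair).
    user_mass : float
        Body mass of the participant, kg.
    gravity : float
        Gravitational acceleration, m·s⁻².
    """

    wheelchair_mass: float
    wheel_radius: float
    rim_radius: float
    user_mass: float
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if not (0 < self.rim_radius <= self.wheel_radius):
            raise InvalidConfigurationError(
                f"need 0 < rim_radius <= wheel_radius, got "
                f"rim={self.rim_radius}, wheel={self.wheel_radius}"
            )
        if self.wheelchair_mass <= 0 or self.user_mass <= 0:
            raise InvalidConfigurationError("masses must be positive")

    @property
    def total_mass(self) -> float:
        """Combined user + wheelchair mass, kg."""
        return self.wheelchair_mass + self.user_mass

    @property
    def total_weight(self) -> float:
        """Combined weight, N (total mass times gravity)."""
        return self.total_mass * self.gravity


def _as_channel(x, n: Optional[int], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise TraceFormatError(f"channel {name!r} must be 1-D")
    if n is not None and arr.size != n:
        raise TraceFormatError(
            f"channel {name!r} has {arr.size} samples, expected {n}"
        )
    return arr


@dataclass
class ErgometerTrace:
    """Uniformly sampled per-side torque/velocity trace.

    ``test_start`` marks t = 0 of the protocol (trigger from the operator or
    the onset rule of :func:`detect_test_start`); all analysis windows are
    anchored there.  ``heart_rate`` is optional and carried on the same
    clock (step-interpolated by the reader when the monitor ran slower).
    """

    time: np.ndarray
    torque_left: np.ndarray
    torque_right: np.ndarray
    velocity_left: np.ndarray
    velocity_right: np.ndarray
    rate: float = 100.0
    heart_rate: Optional[np.ndarray] = None
    test_start: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = _as_channel(self.time, None, "time")
        n = self.time.size
        if n < 2:
            raise TraceFormatError("trace needs at least two samples")
        for name in ("torque_left", "torque_right", "velocity_left", "velocity_right"):
            setattr(self, name, _as_channel(getattr(self, name), n, name))
        if self.heart_rate is not None:
            self.heart_rate = _as_channel(self.heart_rate, n, "heart_rate")
        step = np.diff(self.time)
        bad = np.flatnonzero(np.abs(step - 1.0 / self.rate) > _TIME_TOL)
        if bad.size:
            i = int(bad[0])
            raise TraceFormatError(
                f"non-uniform time step at row {i + 1}: "
                f"dt={step[i]:.9f} s, expected {1.0 / self.rate:.9f} s"
            )
        if min(self.velocity_left.min(), self.velocity_right.min()) < -1e-6:
            raise TraceFormatError("negative wheel velocity (backward rolling?)")
        if self.test_start is not None and not (
            self.time[0] - _TIME_TOL <= self.test_start <= self.time[-1] + _TIME_TOL
        ):
            raise TraceFormatError("test_start outside the recorded time span")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Recorded span, s."""
        return float(self.time[-1] - self.time[0])


@dataclass
class ForcePowerTrace:
    """Per-side force/power derived from an :class:`ErgometerTrace`.

    Aggregate channels follow the outcome definitions: force and velocity
    are side *averages*, power is the side *sum*.
    """

    time: np.ndarray
    rate: float
    force_left: np.ndarray
    force_right: np.ndarray
    power_left: np.ndarray
    power_right: np.ndarray
    velocity_mean: np.ndarray
    heart_rate: Optional[np.ndarray] = None
    test_start: Optional[float] = None
    force_mean: np.ndarray = field(init=False)
    power_total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("force_left", "force_right", "power_left", "power_right",
                     "velocity_mean"):
            _as_channel(getattr(self, name), n, name)
        self.force_mean = 0.5 * (self.force_left + self.force_right)
        self.power_total = self.power_left + self.power_right

    @property
    def n_samples(self) -> int:
        return self.time.size

    def segment(self, start: float, stop: Optional[float] = None) -> "ForcePowerTrace":
        """Sub-trace covering ``[start, stop)`` seconds (absolute time)."""
        t = self.time
        i0 = int(np.searchsorted(t, start - _TIME_TOL))
        i1 = t.size if stop is None else int(np.searchsorted(t, stop - _TIME_TOL))
        if i1 <= i0:
            raise InsufficientDataError(
                f"empty segment [{start}, {stop}) in trace of span "
                f"[{t[0]}, {t[-1]}]"
            )
        hr = None if self.heart_rate is None else self.heart_rate[i0:i1]
        return ForcePowerTrace(
            time=t[i0:i1],
            rate=self.rate,
            force_left=self.force_left[i0:i1],
            force_right=self.force_right[i0:i1],
            power_left=self.power_left[i0:i1],
            power_right=self.power_right[i0:i1],
            velocity_mean=self.velocity_mean[i0:i1],
            heart_rate=hr,
            test_start=self.test_start,
        )

    def after_start(self) -> "ForcePowerTrace":
        """Sub-trace from ``test_start`` (or the beginning) to the end."""
        start = self.time[0] if self.test_start is None else self.test_start
        return self.segment(float(start))


def filter_trace(trace: ErgometerTrace, cutoff: float = 10.0, order: int = 4
                 ) -> ErgometerTrace:
    """Zero-phase low-pass filter the torque and velocity channels.

    A Butterworth filter of the given order and cut-off is applied
    forward–backward (``sosfiltfilt``, odd-reflection edge padding), so the
    pass band is delay-free and the effective attenuation order doubles.
    Time base, rate, ``test_start`` and heart rate are untouched.  Filtered
    velocities are clipped at zero: the rollers cannot turn backwards, and
    zero-phase filtering of a standstill start can undershoot by a few
    mm·s⁻¹.

    Raises
    ------
    InvalidConfigurationError
        If ``cutoff`` is not below the Nyquist frequency.
    InsufficientDataError
        If the trace is too short for the edge padding.
    """
    if cutoff <= 0 or cutoff >= trace.rate / 2.0:
        raise InvalidConfigurationError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={trace.rate / 2} Hz)"
        )
    if order < 1:
        raise InvalidConfigurationError("filter order must be >= 1")
    sos = _signal.butter(order, cutoff, btype="low", fs=trace.rate, output="sos")
    # sosfiltfilt needs padlen < n; its default padlen for an order-4 filter
    # is 3 * (2 * n_sections + 1) = 15 samples each side.
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if trace.n_samples <= padlen or trace.n_samples < 3 * (order + 1):
        raise InsufficientDataError(
            f"trace of {trace.n_samples} samples too short for zero-phase "
            f"filtering (needs > {padlen})"
        )

    def _lp(x: np.ndarray) -> np.ndarray:
        return _signal.sosfiltfilt(sos, x)

    return replace(
        trace,
        torque_left=_lp(trace.torque_left),
        torque_right=_lp(trace.torque_right),
        velocity_left=np.clip(_lp(trace.velocity_left), 0.0, None),
        velocity_right=np.clip(_lp(trace.velocity_right), 0.0, None),
    )


def compute_force_power(trace: ErgometerTrace, setup: WheelchairSetup
                        ) -> ForcePowerTrace:
    """Convert torque/velocity into handrim force and power per side.

    Per side, ``F = M / r_r`` and ``PO = (M / r_w) · v``; aggregates are the
    side-average force and velocity and the side-sum power.  Call
    :func:`filter_trace` first unless raw signals are wanted deliberately.
    """
    f_l = trace.torque_left / setup.rim_radius
    f_r = trace.torque_right / setup.rim_radius
    p_l = trace.torque_left / setup.wheel_radius * trace.velocity_left
    p_r = trace.torque_right / setup.wheel_radius * trace.velocity_right
    return ForcePowerTrace(
        time=trace.time,
        rate=trace.rate,
        force_left=f_l,
        force_right=f_r,
        power_left=p_l,
        power_right=p_r,
        velocity_mean=0.5 * (trace.velocity_left + trace.velocity_right),
        heart_rate=trace.heart_rate,
        test_start=trace.test_start,
    )


def rolling_mean_max(x, window: float, rate: float) -> tuple[float, float]:
    """Maximum mean over every full rolling window, and where it starts.

    The window holds ``round(window * rate)`` samples and slides one sample
    at a time; only complete windows count.  Returns ``(value, start)``
    where ``start`` is the offset in seconds of the first window attaining
    the maximum, measured from the first sample of ``x`` (ties break to the
    earliest window).

    Raises
    ------
    InsufficientDataError
        If the signal is shorter than one window.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window * rate))
    if w < 1:
        raise InvalidConfigurationError("window must cover at least one sample")
    if x.size < w:
        raise InsufficientDataError(
            f"signal of {x.size} samples shorter than window of {w}"
        )
    cs = np.concatenate(([0.0], np.cumsum(x)))
    means = (cs[w:] - cs[:-w]) / w
    m = means.max()
    # earliest window within numerical round-off of the maximum
    tol = max(abs(m), 1.0) * 1e-12
    idx = int(np.flatnonzero(means >= m - tol)[0])
    return float(means[idx]), idx / rate


def detect_test_start(fp: ForcePowerTrace, kind: str = "dynamic",
                      velocity_threshold: float = 0.1,
                      force_threshold: float = 5.0) -> float:
    """Onset rule used when no protocol trigger was recorded.

    Dynamic tests start at the first sample where the side-averaged velocity
    exceeds ``velocity_threshold`` (m·s⁻¹); isometric tests at the first
    sample where the side-averaged force exceeds ``force_threshold`` (N).
    """
    if kind == "isometric":
        above = np.flatnonzero(fp.force_mean > force_threshold)
    elif kind == "dynamic":
        above = np.flatnonzero(fp.velocity_mean > velocity_threshold)
    else:
        raise InvalidConfigurationError(f"unknown onset kind {kind!r}")
    if above.size == 0:
        from .errors import DegenerateTraceError

        raise DegenerateTraceError(
            f"no {kind} onset found (signal never crosses the threshold)"
        )
    return float(fp.time[int(above[0])])
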