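"""Filtering, force/power conversion and the rolling-window kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheelergo.errors import (
    InsufficientDataError,
    InvalidConfigurationError,
    TraceFormatError,
)
from wheelergo.signals import (
    ErgometerTrace,
    WheelchairSetup,
    compute_force_power,
    detect_test_start,
    filter_trace,
    rolling_mean_max,
)

from conftest import make_trace


def brute_rolling_max(x, w):
    """Independent oracle: scan every full window, earliest tie wins."""
    means = [np.mean(x[i:i + w]) for i in range(len(x) - w + 1)]
    best = max(means)
    return best, means.index(best)


class TestFilterTrace:
    def test_dc_gain_is_unity_on_constant_torque(self):
        tr = filter_trace(make_trace(torque=10.0, velocity=1.0, duration=5))
        interior = slice(50, -50)
        assert np.allclose(tr.torque_left[interior], 10.0, atol=1e-6)
        assert np.allclose(tr.torque_right[interior], 10.0, atol=1e-6)

    def test_stopband_attenuation_and_passband_preservation(self):
        # 1 Hz kept within 1%, 40 Hz attenuated below 1% (FFT oracle)
        rate, dur = 100.0, 20.0
        t = np.arange(int(dur * rate)) / rate
        sig = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 40.0 * t)
        tr = make_trace(torque=sig, velocity=np.zeros_like(sig), rate=rate,
                        duration=dur)
        out = filter_trace(tr).torque_left
        spec = np.abs(np.fft.rfft(out)) / (len(out) / 2)
        freqs = np.fft.rfftfreq(len(out), 1 / rate)
        amp_at = lambda f: spec[np.argmin(np.abs(freqs - f))]
        assert amp_at(1.0) == pytest.approx(1.0, rel=0.01)
        assert amp_at(40.0) < 0.01

    def test_zero_phase_keeps_peak_location(self):
        # symmetric triangular pulse: filtered peak must not shift
        n = 1000
        pulse = np.concatenate([np.linspace(0, 5, 100),
                                np.linspace(5, 0, 100)[1:],
                                np.zeros(n - 199)])
        pulse = np.roll(pulse, 400)
        tr = make_trace(torque=pulse, velocity=np.zeros(n), duration=10)
        out = filter_trace(tr).torque_left
        assert abs(int(np.argmax(out)) - int(np.argmax(pulse))) <= 1

    def test_heart_rate_is_not_filtered(self):
        hr = np.tile([120.0, 140.0], 250)
        tr = filter_trace(make_trace(torque=1.0, velocity=1.0, duration=5,
                                     heart_rate=hr))
        assert np.array_equal(tr.heart_rate, hr)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            filter_trace(make_trace(duration=5), cutoff=60.0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            filter_trace(make_trace(duration=0.1))


class TestComputeForcePower:
    def test_force_from_torque_and_rim_radius(self, setup):
        fp = compute_force_power(make_trace(torque=3.1, velocity=0.0), setup)
        assert np.allclose(fp.force_left, 10.0)
        assert np.allclose(fp.force_mean, 10.0)

    def test_power_from_torque_wheel_radius_velocity(self, setup):
        fp = compute_force_power(make_trace(torque=3.4, velocity=2.0), setup)
        assert np.allclose(fp.power_left, 20.0)
        assert np.allclose(fp.power_right, 20.0)
        assert np.allclose(fp.power_total, 40.0)

    def test_force_power_algebraic_identity(self, setup):
        rng = np.random.default_rng(3)
        n = 500
        tr = make_trace(torque=rng.uniform(0, 30, n),
                        velocity=rng.uniform(0, 3, n), duration=5)
        fp = compute_force_power(tr, setup)
        ratio = setup.rim_radius / setup.wheel_radius
        per_side = fp.force_left * ratio * tr.velocity_left
        assert np.allclose(per_side, fp.power_left, rtol=1e-9)
        assert np.allclose(fp.power_total, fp.power_left + fp.power_right,
                           rtol=1e-12)

    def test_mismatched_channels_rejected(self):
        with pytest.raises(TraceFormatError):
            ErgometerTrace(time=np.arange(5) / 100.0,
                           torque_left=np.zeros(5), torque_right=np.zeros(4),
                           velocity_left=np.zeros(5), velocity_right=np.zeros(5))


class TestRollingMeanMax:
    def test_constant_signal(self):
        value, start = rolling_mean_max(np.full(100, 5.0), 2.0, 10.0)
        assert value == pytest.approx(5.0)
        assert start == 0.0

    def test_small_example_enumerated(self):
        value, start = rolling_mean_max([0, 0, 10, 10, 0], 2.0, 1.0)
        assert value == pytest.approx(10.0)
        assert start == pytest.approx(2.0)  # third sample

    def test_increasing_ramp_anchors_at_latest_start(self):
        x = np.arange(50, dtype=float)
        value, start = rolling_mean_max(x, 1.0, 10.0)
        ref_value, ref_idx = brute_rolling_max(x, 10)
        assert value == pytest.approx(ref_value)
        assert start == pytest.approx(ref_idx / 10.0)
        assert ref_idx == 40  # latest admissible start

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            rolling_mean_max(np.ones(10), 2.0, 10.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=60),
           st.integers(1, 10))
    def test_agrees_with_brute_force(self, xs, w):
        x = np.asarray(xs)
        if w > x.size:
            w = x.size
        value, start = rolling_mean_max(x, float(w), 1.0)
        ref_value, ref_idx = brute_rolling_max(x, w)
        assert value == pytest.approx(ref_value, rel=1e-9, abs=1e-9)
        # the reported window must attain the maximum
        attained = np.mean(x[int(start):int(start) + w])
        assert attained == pytest.approx(ref_value, rel=1e-9, abs=1e-9)


class TestTraceValidation:
    def test_non_uniform_step_names_first_bad_row(self):
        t = np.arange(10) / 100.0
        t[5] += 0.004
        with pytest.raises(TraceFormatError, match="row"):
            ErgometerTrace(time=t, torque_left=np.zeros(10),
                           torque_right=np.zeros(10),
                           velocity_left=np.zeros(10),
                           velocity_right=np.zeros(10))

    def test_test_start_outside_span_rejected(self):
        with pytest.raises(TraceFormatError):
            make_trace(duration=2.0, test_start=5.0)


class TestOnsetDetection:
    def test_dynamic_onset_at_velocity_threshold(self, setup):
        v = np.concatenate([np.zeros(100), np.linspace(0, 2, 400)])
        tr = make_trace(torque=1.0, velocity=v, duration=5, test_start=None)
        fp = compute_force_power(tr, setup)
        onset = detect_test_start(fp, "dynamic")
        assert 1.0 <= onset <= 1.3

    def test_isometric_onset_at_force_threshold(self, setup):
        tq = np.concatenate([np.zeros(200), np.full(300, 31.0)])
        tr = make_trace(torque=tq, velocity=np.zeros(500), duration=5,
                        test_start=None)
        fp = compute_force_power(tr, setup)
        assert detect_test_start(fp, "isometric") == pytest.approx(2.0)
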