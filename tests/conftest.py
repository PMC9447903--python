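import numpy as np
import pytest

from wheelergo.signals import ErgometerTrace, ForcePowerTrace, WheelchairSetup


@pytest.fixture
def setup():
    """Reference tennis wheelchair under a 70 kg user."""
    return WheelchairSetup(wheelchair_mass=10.0, wheel_radius=0.34,
                           rim_radius=0.31, user_mass=70.0)


def make_trace(torque=0.0, velocity=0.0, duration=10.0, rate=100.0,
               heart_rate=None, test_start=0.0):
    """Constant-channel ergometer trace (scalars or arrays per channel)."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    full = lambda x: np.full(n, float(x)) if np.ndim(x) == 0 else np.asarray(x, float)
    hr = None if heart_rate is None else full(heart_rate)
    return ErgometerTrace(
        time=t, torque_left=full(torque), torque_right=full(torque),
        velocity_left=full(velocity), velocity_right=full(velocity),
        rate=rate, heart_rate=hr, test_start=test_start,
    )


def make_fp(power_total, velocity=0.0, force_mean=0.0, rate=100.0,
            heart_rate=None, test_start=0.0, duration=None):
    """ForcePowerTrace straight from aggregate channels (split evenly)."""
    p = np.asarray(power_total, dtype=float)
    if p.ndim == 0:
        n = int(round((duration or 10.0) * rate))
        p = np.full(n, float(p))
    n = p.size
    t = np.arange(n) / rate
    full = lambda x: np.full(n, float(x)) if np.ndim(x) == 0 else np.asarray(x, float)
    hr = None if heart_rate is None else full(heart_rate)
    return ForcePowerTrace(
        time=t, rate=rate,
        force_left=full(force_mean), force_right=full(force_mean),
        power_left=p / 2.0, power_right=p / 2.0,
        velocity_mean=full(velocity), heart_rate=hr, test_start=test_start,
    )


@pytest.fixture
def table1():
    from wheelergo.io import load_table1

    return load_table1()
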