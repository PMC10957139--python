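import numpy as np
import pytest

from earmotion.imu_core import ImuTrace
from earmotion.synthetic import NoiseSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """4 participants x 9 classes x 25 s at 100 Hz, default sensor noise."""
    return simulate_dataset(4, per_class_duration_s=25.0, seed=42)


@pytest.fixture()
def static_trace():
    """2 s of a perfectly level, noise-free sensor."""
    n = 200
    accel = np.tile([0.0, 0.0, 1.0], (n, 1))
    gyro = np.zeros((n, 3))
    return ImuTrace(accel=accel, gyro=gyro, fs=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
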