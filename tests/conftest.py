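import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gammaloop as gl

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_model():
    return gl.reference_arx_model()


@pytest.fixture(scope="session")
def demo():
    return gl.demo_plant()


@pytest.fixture(scope="session")
def step2000():
    return gl.step_stimulus(2000, amplitude=2.0)


@pytest.fixture(scope="session")
def reference_trials(reference_model, step2000):
    """10 reference-process gamma-power trials, 4 s at 500 Hz."""
    t, X = gl.reference_power_trials(10, base_seed=1234)
    return t, X


@pytest.fixture(scope="session")
def wavelet_spec():
    return gl.WaveletBankSpec()


@pytest.fixture(scope="session")
def wavelet_bank(wavelet_spec):
    return gl.build_wavelet_bank(wavelet_spec)


@pytest.fixture(scope="session")
def printed_gain_model():
    """Stable plant with the published input gains and DC denominator
    exactly 2, for closed-form steady-state arithmetic."""
    return gl.ARXModel(a=(0.5, 0.5, 0.0, 0.0, 0.0, 0.0),
                       b_dc=3.4689e-4, b_s=8.7828e-5,
                       noise_variance=3.7197e-7)


def tone(freq_hz, duration_s=4.0, fs=500.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.cos(2 * np.pi * freq_hz * t + phase)
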