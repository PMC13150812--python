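import numpy as np
import pytest

from swim2d.config import InstrumentConfig
from swim2d.forward_sim import FragChannel, IonSpecies, SimulationConfig, generate_cube


@pytest.fixture(scope="session")
def full_scale_cfg():
    """Full-scale instrument settings (1 MHz trap, 10-500 kHz band, 1024 indices)."""
    return InstrumentConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale settings for fast tests: shorter pulses, 64 indices."""
    return InstrumentConfig(
        dac_rate=2.5e6, pulse_duration=2.0e-3, T=0.8e-3, n_indices=64
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def quiet_sim(**kw):
    """Noiseless, baseline-free simulation config for oracle bookkeeping."""
    base = dict(noise_prop=0.0, noise_floor=0.0, upstream_frac=0.0, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def quiet_sim_factory():
    return quiet_sim


def cross_spectrum_phase(a, b, fe):
    """Phase of trace a relative to trace b at frequency fe (cycles/index)."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    n = len(a)
    k = int(round(fe * n))
    fa = np.fft.rfft(a)[k]
    fb = np.fft.rfft(b)[k]
    return float(np.angle(fa * np.conj(fb)))


@pytest.fixture(scope="session")
def phase_at():
    return cross_spectrum_phase
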