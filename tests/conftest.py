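import numpy as np
import pytest

from nicedwi import DWISeries, forward_signal, sample_rician

BVALUES = np.array([50.0, 600.0, 900.0])
M = 9


def make_clean_series(shape=(4, 3, 2), S0=100.0, ADC=1.1e-3, bvalues=BVALUES, M=M):
    """Noise-free per-excitation series: exact monoexponential everywhere."""
    full_b = np.repeat(bvalues, M)
    sig = forward_signal(S0, ADC, full_b)
    vol = np.broadcast_to(sig, shape + (full_b.size,)).copy()
    return DWISeries(signal=vol, bvalues=full_b)


def make_noisy_series(shape=(8, 8, 2), S0=1.0, ADC=1.0e-3, snr=50.0,
                      bvalues=BVALUES, M=M, seed=0):
    """Rician-noised per-excitation series at uniform true parameters."""
    rng = np.random.default_rng(seed)
    full_b = np.repeat(bvalues, M)
    mu = np.broadcast_to(forward_signal(S0, ADC, full_b), shape + (full_b.size,))
    noisy = sample_rician(mu, S0 / snr, mu.shape, rng)
    return DWISeries(signal=noisy, bvalues=full_b)


@pytest.fixture
def clean_series():
    return make_clean_series()


@pytest.fixture
def noisy_series():
    return make_noisy_series()
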