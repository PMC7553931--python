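"""Shared fixtures: small forward models and trained decoders.

Session-scoped so the expensive fits run once.  Problem sizes are kept
small (4-8 channels, 1-2 training blocks) — the pipeline is identical
to the full 32-channel protocol, only cheaper.
"""

import numpy as np
import pytest

import cvep

PANGRAM = "THE QUICK BROWN FOX JUMPS OVER THE LAZY DOG"


@pytest.fixture(scope="session")
def cb32():
    return cvep.default_codebook(32)


@pytest.fixture(scope="session")
def cb4():
    return cvep.default_codebook(4)


@pytest.fixture(scope="session")
def clean_model32(cb32):
    """Noise-free forward model, 8 channels."""
    return cvep.make_forward_model(8, 600.0, snr=np.inf, alpha_amp=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_trials32(clean_model32, cb32):
    return cvep.simulate_training_set(clean_model32, cb32, n_b=1, seed=12)


@pytest.fixture(scope="session")
def clean_results32(clean_trials32, cb32):
    return cvep.CvepDecoder(clean_trials32, cb32).fit()


@pytest.fixture(scope="session")
def clean_model4(cb4):
    return cvep.make_forward_model(4, 600.0, snr=np.inf, alpha_amp=0.0, seed=13)


@pytest.fixture(scope="session")
def clean_results4(clean_model4, cb4):
    trials = cvep.simulate_training_set(clean_model4, cb4, n_b=1, seed=14)
    return cvep.CvepDecoder(trials, cb4).fit()


@pytest.fixture(scope="session")
def noisy_results32(cb32):
    """Decoder trained at a realistic operating point (snr 0.3)."""
    fm = cvep.make_forward_model(8, 600.0, snr=0.3, alpha_amp=0.5, seed=21)
    trials = cvep.simulate_training_set(fm, cb32, n_b=2, seed=22)
    return fm, cvep.CvepDecoder(trials, cb32).fit()


@pytest.fixture(scope="session")
def pangram():
    return PANGRAM
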