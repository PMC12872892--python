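import logging

import pytest

from fertimass.io import RunConfig
from fertimass.pipeline import analyze_dataset
from fertimass.synthetic import TrialConfig, simulate_trial

# Warnings from intentionally degenerate inputs would flood the test log.
logging.getLogger("fertimass").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Default trial layout with all measurement noise and jitter off."""
    return simulate_trial(TrialConfig().zero_noise(), seed=0)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default trial layout at default noise levels."""
    return simulate_trial(TrialConfig(), seed=0)


@pytest.fixture(scope="session")
def zero_noise_bundle(zero_noise_dataset):
    return analyze_dataset(zero_noise_dataset, RunConfig())


@pytest.fixture(scope="session")
def noisy_bundle(noisy_dataset):
    return analyze_dataset(noisy_dataset, RunConfig())
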