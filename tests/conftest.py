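import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import enose as en

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def signatures():
    return en.default_signatures()


@pytest.fixture(scope="session")
def dataset(signatures):
    """The standard protocol: 4 substances x 5 campaigns x 300 samples."""
    return en.simulate_dataset(
        signatures, n_campaigns=5,
        noise_schedule=en.default_noise_schedule(5), seed=42,
    )


@pytest.fixture(scope="session")
def processed(dataset):
    return [en.preprocess_session(s) for s in dataset]


@pytest.fixture(scope="session")
def quiet_session(signatures):
    """One noiseless, driftless session — exact-arithmetic fixture."""
    noise = en.SessionNoiseSpec(baseline=500.0, drift_slope=0.0,
                                noise_sd=0.0, seed=0)
    return en.simulate_session(signatures[0], noise)
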