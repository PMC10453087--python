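import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sersnet import GeneratorConfig, WavenumberGrid  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Generator with all stochastic terms and background switched off."""
    return GeneratorConfig(
        noise_sd=0.0, replicate_log_sd=0.0, baseline_amplitude=0.0, baseline_tilt=0.0
    )


@pytest.fixture
def small_dataset_config():
    """Reduced-scale dataset (48 spectra) for fast end-to-end tests."""
    return GeneratorConfig(samples_per_class=4, replicates_per_sample=3, seed=99)


@pytest.fixture
def coarse_grid():
    return WavenumberGrid(300.0, 1800.0, 376)
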