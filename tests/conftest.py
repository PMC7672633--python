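import numpy as np
import pytest
from hypothesis import settings

from floatcall.synth import gen_benchmark_scene, gen_noise

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def benchmark_scene():
    """20 high-SNR D-calls in 30 min of noise at 200 Hz, seeded."""
    return gen_benchmark_scene(seed=1)


@pytest.fixture(scope="session")
def noise_30min():
    return gen_noise(1800.0, 200.0, 0.05, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
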