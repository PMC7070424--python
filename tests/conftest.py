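import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from irsring import DetectorConfig, FrontEndConfig, build_ring

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ring1():
    return build_ring("IRSR1")


@pytest.fixture(scope="session")
def ring2():
    return build_ring("IRSR2")


@pytest.fixture(scope="session")
def fe_quiet():
    """Front end with the noise source switched off."""
    return FrontEndConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def fe_default():
    return FrontEndConfig()


def flat_signal(level: int = 512, n: int = 300) -> np.ndarray:
    return np.full((16, n), level, dtype=np.uint16)


def add_pulse(counts: np.ndarray, channel: int, start: int, length: int,
              height: int) -> np.ndarray:
    counts = counts.copy()
    counts[channel, start:start + length] += height
    return counts


@pytest.fixture
def st100():
    return DetectorConfig(threshold=100)
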