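import numpy as np
import pytest

from crestscan import GeneratorSpec, HydropathyConfig, ScanConfig


@pytest.fixture
def spec():
    return GeneratorSpec()


@pytest.fixture
def scan_config():
    return ScanConfig()


@pytest.fixture
def hyd_config():
    return HydropathyConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
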