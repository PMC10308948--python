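import numpy as np
import pytest

from lvcheck import LogisticParams, LVSystem, NoiseModel
from lvcheck.simulate import table_pair_system


@pytest.fixture(scope="session")
def pair_system() -> LVSystem:
    """The reference two-isolate system used across the docs and tests."""
    return table_pair_system()


@pytest.fixture(scope="session")
def no_noise() -> NoiseModel:
    return NoiseModel.none()


@pytest.fixture(scope="session")
def std_noise() -> NoiseModel:
    """Realistic plate-reader noise: 2% lognormal + 0.003 OD read noise."""
    return NoiseModel(multiplicative_sd=0.02, additive_sd=0.003)


@pytest.fixture(scope="session")
def mult_noise() -> NoiseModel:
    return NoiseModel(multiplicative_sd=0.02, additive_sd=0.0)


@pytest.fixture(scope="session")
def ten_min_grid_48h() -> np.ndarray:
    return np.arange(0, 48 * 6 + 1) / 6.0
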