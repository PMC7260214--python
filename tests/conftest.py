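import numpy as np
import pytest

from methylkin.error_models import ErrorModelSpec
from methylkin.model_core import ModelConfig, build_trace_bank
from methylkin.rate_inference import build_grid


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def grid(config):
    return build_grid(config)


@pytest.fixture(scope="session")
def bank(grid, config):
    return build_trace_bank(grid, config)


@pytest.fixture(scope="session")
def bb_error():
    return ErrorModelSpec(kind="betabinomial", gamma=0.0055)


@pytest.fixture(scope="session")
def binom_error():
    return ErrorModelSpec(kind="binomial")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
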