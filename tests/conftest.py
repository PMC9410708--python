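import numpy as np
import pytest

from osmoscale import GeneratorConfig, ModelParams


@pytest.fixture
def yeast_params() -> ModelParams:
    """Zero-tension parameter set with a 7.5% nuclear osmolyte fraction.

    Matched normalized dry volumes (bN/bC equals the nuclear amount
    fraction) and an isotonic state of VC = 100 um^3 at 500 mOsm.
    """
    return ModelParams(NN=2812.5, NCy=34687.5, bN=1.875, bC=25.0)


@pytest.fixture
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=20240901)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
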