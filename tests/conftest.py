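import numpy as np
import pytest

from fecgkit.io import PipelineConfig
from fecgkit.synthetic import SyntheticConfig, synthesize_aecg


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_aecg():
    """The default study recording: 120 s, 3 channels, 500 Hz, seed 1."""
    return synthesize_aecg(SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def short_aecg():
    """A 60 s recording for tests that only need a shorter run."""
    return synthesize_aecg(SyntheticConfig(rng_seed=1, duration_s=60.0))
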