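import numpy as np
import pytest

from crseawater import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=20260926)


@pytest.fixture(scope="session")
def survey(default_config):
    """One full synthetic survey shared across tests (read-only)."""
    return generate_survey(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
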