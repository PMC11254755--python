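import numpy as np
import pytest

from chemres import (
    CRNSpec,
    FlowSettings,
    ReservoirConfig,
    generate_random_crn,
    make_constant_profile,
)


@pytest.fixture(scope="session")
def settings() -> FlowSettings:
    return FlowSettings()


@pytest.fixture(scope="session")
def default_crn() -> CRNSpec:
    """The fixture reservoir network used across integration tests."""
    return generate_random_crn(seed=0)


@pytest.fixture(scope="session")
def quiet_config() -> ReservoirConfig:
    """Noise-free identity observation for closed-form checks."""
    return ReservoirConfig(noise_cv=0.0, noise_floor=0.0, identity_observation=True)


@pytest.fixture(scope="session")
def inert_crn() -> CRNSpec:
    """A single inert species fed by the DHA channel: pure-flow dynamics."""
    return CRNSpec(species=["A"], reactions=[], input_map={"dha": "A"})


@pytest.fixture
def constant_profile(settings):
    return make_constant_profile({"dha": 50.0}, duration_s=600.0, settings=settings)


@pytest.fixture
def rng() -> np.random.Generator:
    """Fresh seeded generator per test: results are order-independent."""
    return np.random.default_rng(12345)
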