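import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


@pytest.fixture(scope="session")
def default_config():
    from mirkey import SyntheticConfig

    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def fixture_bundle(default_config):
    """One in-memory synthetic input bundle shared across tests."""
    from mirkey.pipeline import synthetic_inputs

    return synthetic_inputs(default_config)
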