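import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# placement-skip warnings on finite fixtures are expected and noisy
logging.getLogger("bescreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_ab():
    from bescreen import fixture_AB

    return fixture_AB()


@pytest.fixture(scope="session")
def fixture_c():
    from bescreen import fixture_C

    return fixture_C()


@pytest.fixture(scope="session")
def registry():
    from bescreen import default_registry

    return default_registry()
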