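import pytest
from hypothesis import HealthCheck, settings

from brickmatch import default_library, figure_fixture, figure_names

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def figures():
    return {name: figure_fixture(name) for name in figure_names()}
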