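import pytest
from hypothesis import settings

from cfscreen import PopulationParams, ScreeningPolicy

settings.register_profile("ci", derandomize=True, max_examples=100, database=None)
settings.load_profile("ci")


@pytest.fixture
def pop() -> PopulationParams:
    return PopulationParams()


@pytest.fixture
def policy() -> ScreeningPolicy:
    return ScreeningPolicy(c1=51.0, n=32000)
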