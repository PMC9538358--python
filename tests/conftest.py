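import pytest
from hypothesis import settings

from ltcifund import SyntheticSpec, default_parameter_set

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_params():
    return default_parameter_set(SyntheticSpec(scale_preset="toy"))


@pytest.fixture(scope="session")
def china_params():
    return default_parameter_set(SyntheticSpec(scale_preset="china_scale"))
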