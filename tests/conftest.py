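import pytest
from hypothesis import HealthCheck, settings

import whiteflysim as w

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    return w.default_parameters()


@pytest.fixture(scope="session")
def standard_run(default_params):
    """The documented standard condition: 100 adults on 125 sq.in., 7 weeks."""
    return w.simulate(w.inoculation_state(), default_params, w.HARVEST_WEEK_DEFAULT)
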