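import pytest
from hypothesis import HealthCheck, settings

import nsclc_cea as nc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return nc.default_parameters()


@pytest.fixture(scope="session")
def base_outcomes(params):
    return {s: nc.evaluate_strategy(s, params) for s in nc.STRATEGIES}
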