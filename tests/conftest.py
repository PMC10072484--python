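import pytest
from hypothesis import HealthCheck, settings

import transmitbias as tb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def observed_counts() -> tb.CountTable:
    """The experiment's four production counts (E2N 27/3, P2P 14/18)."""
    return tb.CountTable.from_four_counts(27, 3, 14, 18)


@pytest.fixture
def post_exclusion_design() -> tb.ExperimentDesign:
    """30 expert-to-novice + 32 peer-to-peer participants."""
    return tb.ExperimentDesign(30, 32)
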