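import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mate.io_types import FatigueTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_table() -> FatigueTable:
    """2x2 S-N surface small enough for hand interpolation."""
    return FatigueTable(
        load_levels=[30.0, 50.0],
        cycle_levels=[10.0, 1000.0],
        probability=[[0.0, 0.1], [0.2, 0.6]],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
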