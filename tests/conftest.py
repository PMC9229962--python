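import pytest
from hypothesis import HealthCheck, settings

from fuzzymotion import CalibrationConstants, build_grid, default_rule_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def calib():
    """Symmetric demo anchors: x_n = -1 V, x_o = 0 V, x_p = +1 V."""
    return CalibrationConstants(-1.0, 0.0, 1.0)


@pytest.fixture
def grid(calib):
    return build_grid(calib)


@pytest.fixture(scope="session")
def table():
    return default_rule_table()
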