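import numpy as np
import pytest
from hypothesis import settings

from skytrace.environment import EnvironmentState, WindConfig

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calm_env():
    """Environment with no wind, no thermal, no obstacles."""
    wind = WindConfig(w_base=np.zeros(3), sigma_gust=0.0, thermal_strength=0.0)
    return EnvironmentState(wind=wind, goal=np.array([1000.0, 0.0, 40.0]),
                            h_pref=40.0)
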