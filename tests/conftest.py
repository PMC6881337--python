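import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    from deepvnc import make_scene

    return make_scene(48, 48, seed=7)


@pytest.fixture
def noiseless_physics():
    from deepvnc import noiseless, physics_preset

    return noiseless(physics_preset("80/150Sn"))
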