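import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geometry():
    from axodyn import AxonGeometry

    return AxonGeometry()


@pytest.fixture
def small_geometry():
    from axodyn import AxonGeometry

    return AxonGeometry(terminal_length_um=30.0, pixel_size_um=0.25, origin_um=(5.0, 7.0))
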