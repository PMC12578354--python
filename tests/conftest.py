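import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mesh42():
    """Uniform 1D mesh with 42 elements on [0, 1000] μm (43 nodes)."""
    from scratchpde.fem import interval_mesh

    return interval_mesh(np.linspace(0.0, 1000.0, 43))
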