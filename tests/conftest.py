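import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gaussian_op():
    """8x8 image measured at 50% by an orthonormal-row Gaussian matrix."""
    from epgn import make_gaussian_operator

    return make_gaussian_operator(64, 0.5, seed=1, image_shape=(8, 8))


@pytest.fixture(scope="session")
def phantoms():
    from epgn import PhantomSpec, make_phantoms

    return make_phantoms(PhantomSpec(size=(64, 64), seed=0), 8)
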