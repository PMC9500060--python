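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


def random_blob(rng, shape, p=0.5, smooth=True):
    """A random-ish blobby boolean mask (connected enough to have surface)."""
    arr = rng.random(shape) < p
    if smooth:
        from scipy import ndimage

        arr = ndimage.binary_closing(arr)
    return arr


@pytest.fixture(scope="session")
def noiseless_scene():
    """One shared noiseless default phantom (seed 7)."""
    import liverseg as ls

    return ls.generate_phantom(ls.default_spec(seed=7, noise_std=0.0))
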