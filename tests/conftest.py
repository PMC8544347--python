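import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "taphen",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("taphen")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_rgb(pixels, bit_depth=8, **kwargs):
    """Convenience wrapper building a MultichannelImage from any int array."""
    from taphen.imgio import MultichannelImage

    arr = np.asarray(pixels)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return MultichannelImage(arr.astype(dtype), bit_depth=bit_depth, **kwargs)


@pytest.fixture(scope="session")
def membrane_scene():
    """One noise-free small dual-stain scene shared across tests."""
    from taphen import synthgen

    spec = synthgen.preset_spec("membrane", small=True, seed=7, noise_model="none")
    return synthgen.generate_scene(spec)
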