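import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paindraw import generate_reference

settings.register_profile(
    "paindraw",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("paindraw")


@pytest.fixture(scope="session")
def ref_and_mask():
    """A 160x120 synthetic two-figure reference with its ground-truth mask."""
    return generate_reference(160, 120, seed=1)


@pytest.fixture(scope="session")
def ref(ref_and_mask):
    return ref_and_mask[0]


@pytest.fixture(scope="session")
def body_mask(ref_and_mask):
    return ref_and_mask[1]


def random_blob_raster(rng, h, w, p_white=0.6):
    """Random RGB raster of pure white / black / gray pixels."""
    choices = np.array(
        [[255, 255, 255], [0, 0, 0], [180, 180, 180]], dtype=np.uint8
    )
    idx = rng.choice(3, size=(h, w), p=[p_white, 0.3, 0.1])
    return choices[idx]
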