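import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_image():
    """2x2 image with grey levels {0, 50, 100, 200}."""
    from octlayers import BScanImage

    return BScanImage(np.array([[0.0, 50.0], [100.0, 200.0]]), max_grey=256)


@pytest.fixture
def flat_phantom_spec():
    """Noise-free step-profile phantom: flat interfaces, no speckle/vessels."""
    from octlayers import PhantomSpec

    return PhantomSpec(
        speckle_looks=None, vessels=[], slope_px=0.0, curve_px=0.0, seed=1
    )
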