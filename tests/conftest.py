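import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_4f():
    """The introductory 4f relay: f = 50/50, lens diameters 10, camera 10."""
    from paraxial import ImagingPath, make_aperture, make_space, make_thin_lens

    path = ImagingPath(label="4f example")
    path.append(make_space(50.0))
    path.append(make_thin_lens(50.0, diameter=10.0, label="First lens"))
    path.append(make_space(100.0))
    path.append(make_thin_lens(50.0, diameter=10.0, label="Second lens"))
    path.append(make_space(50.0))
    path.append(make_aperture(10.0, label="Camera"))
    return path
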