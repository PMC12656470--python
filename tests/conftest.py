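import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def square_image():
    """480x640 scene with one bright axis-aligned square on a plain background."""
    img = np.full((480, 640), 0.35)
    img[120:280, 200:360] = 0.8
    return img


@pytest.fixture(scope="session")
def square_maps(square_image):
    from gocao.matching import feature_pipeline

    return feature_pipeline(square_image)


@pytest.fixture(scope="session")
def disk_image():
    yy, xx = np.mgrid[:160, :160]
    return (((xx - 80) ** 2 + (yy - 80) ** 2) <= 45**2).astype(float)


@pytest.fixture(scope="session")
def synthetic_pair():
    """One default ground-truthed visible/infrared pair (illumination #2)."""
    from gocao.synthetic import ScenePairSpec, generate_pair

    return generate_pair(ScenePairSpec(seed=2, illumination_level=2))


@pytest.fixture(scope="session")
def registered_pair(synthetic_pair):
    from gocao.matching import register_pair

    vis, ir, truth = synthetic_pair
    return register_pair(vis, ir, seed=1), truth
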