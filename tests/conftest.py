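import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from facemark.geometry import EyePair, FaceGeometry
from facemark.synthface import FaceSpec


@pytest.fixture
def circle_geom() -> FaceGeometry:
    return FaceGeometry((100.0, 100.0), 90.0, 90.0)


@pytest.fixture
def ellipse_geom() -> FaceGeometry:
    return FaceGeometry((100.0, 120.0), 80.0, 100.0)


@pytest.fixture
def eyes() -> EyePair:
    return EyePair((40.0, 50.0), (80.0, 50.0))


@pytest.fixture
def face_spec() -> FaceSpec:
    return FaceSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
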