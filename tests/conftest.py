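import numpy as np
import pytest

from urbanrat.geometry import CameraParams
from urbanrat.movement import NoiseParams
from urbanrat.simulate import SceneSimConfig, SizeMixture


@pytest.fixture
def camera() -> CameraParams:
    return CameraParams(focal_length=800.0, tilt_angle=0.35, plane_offset=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene_cfg() -> SceneSimConfig:
    """A fast 3-animal scene for unit tests (full-size runs live in acceptance)."""
    return SceneSimConfig(n_animals=3, n_frames=60, seed=7)


def random_camera(rng: np.random.Generator) -> CameraParams:
    return CameraParams(
        focal_length=float(rng.uniform(300, 1500)),
        tilt_angle=float(rng.uniform(0.1, 1.2)),
        plane_offset=float(rng.uniform(1.0, 10.0)),
    )
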