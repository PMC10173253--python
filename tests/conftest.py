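import numpy as np
import pytest

from proximap import PointCloud, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def cloud_2d_small() -> PointCloud:
    """20 uniform points in 2D — small enough for brute-force oracles."""
    return generate_scene(SceneConfig(dimension=2, n_points=20, seed=42))


@pytest.fixture(scope="session")
def cloud_2d_200() -> PointCloud:
    """200 uniform points in 2D for exact generator/oracle comparison."""
    return generate_scene(SceneConfig(dimension=2, n_points=200, seed=7))


@pytest.fixture(scope="session")
def cloud_3d_200() -> PointCloud:
    return generate_scene(SceneConfig(dimension=3, n_points=200, seed=8))


def random_similarity(dim: int, rng: np.random.Generator):
    """Random rotation/reflection + positive scale + translation."""
    m = rng.normal(size=(dim, dim))
    q, _ = np.linalg.qr(m)
    scale = rng.uniform(0.3, 4.0)
    shift = rng.normal(size=dim) * 3
    return q * scale, shift


def apply_map(cloud: PointCloud, matrix: np.ndarray, shift: np.ndarray) -> PointCloud:
    return PointCloud(cloud.node_ids, cloud.coordinates @ matrix.T + shift)
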