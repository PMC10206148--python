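import numpy as np
import pytest

from benthofind import (SceneConfig, SegmentationParams, extract_patches,
                        generate_scene, segment_image)


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """Small scenes for fast unit tests (module-scale behavior only)."""
    return SceneConfig(image_size=(96, 96), nodule_density=15.0, fauna_rate=1.0,
                       laser_rate=0.3, dark_patch_rate=0.1, seed=11)


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneConfig(seed=5), 0)


@pytest.fixture(scope="session")
def scene_patches(default_scene):
    params = SegmentationParams()
    labels = segment_image(default_scene.image, params)
    return extract_patches(default_scene.image, labels, params, 64,
                           default_scene.scene_id)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def make_colored_patches(n: int, color, noise: float, size: int = 32,
                         seed: int = 0) -> list[np.ndarray]:
    """Square patches of one base color plus pixel noise, for toy fixtures."""
    r = np.random.default_rng(seed)
    base = np.asarray(color, dtype=float)
    return [np.clip(base + r.normal(0, noise, size=(size, size, 3)), 0, 1)
            for _ in range(n)]
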