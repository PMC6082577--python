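import numpy as np
import pytest

from focikit import ImageStack, SceneSpec


@pytest.fixture
def planted_block_plane() -> np.ndarray:
    """16x16 uniform background of 100 with a 3x3 block of 1000 at rows/cols 6-8."""
    plane = np.full((16, 16), 100, dtype=np.uint16)
    plane[6:9, 6:9] = 1000
    return plane


@pytest.fixture
def planted_block_stack(planted_block_plane) -> ImageStack:
    return ImageStack(pixels=planted_block_plane[None, None, None])


@pytest.fixture
def tiny_scene_spec() -> SceneSpec:
    """A scene small enough for per-test generation."""
    return SceneSpec(image_shape=(128, 128), n_cells=6, n_z=2, layout="uniform", seed=11)
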