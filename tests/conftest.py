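import numpy as np
import pytest

from pestnet.attention import AttentionBox, CropConfig
from pestnet.model import BackboneConfig, CascadeModel
from pestnet.synthetic import SceneSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """32 px scenes: cheap enough for per-test generation."""
    return SceneSpec(image_size=32, n_classes=3, patch_half_len_range=(4, 6),
                     clutter_density=3.0, noise_sd=0.02, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec, {"train": 12, "validation": 6, "test": 4})


@pytest.fixture(scope="session")
def small_model():
    cfg = BackboneConfig(channels=(4, 8, 8, 8, 8), input_size=32, n_classes=3)
    return CascadeModel(cfg, seed=3)


@pytest.fixture
def unit_box():
    return AttentionBox(tx=100.0, ty=80.0, tl=30.0)


@pytest.fixture
def crop_cfg():
    return CropConfig(steepness=10.0, out_size=32, min_half_len=4.0)
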