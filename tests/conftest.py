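import numpy as np
import pytest

import scmpmixer as sm
from scmpmixer.data import ImageSet
from scmpmixer.model import ModelConfig
from scmpmixer.swin_core import SwinBlockConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_model_config(variant: str = "full", num_classes: int = 3,
                      seed: int = 1) -> ModelConfig:
    """Smallest configuration that exercises every architectural path:
    input 32, token grids 8/4, window 4, 16-wide tokens."""
    return ModelConfig(
        num_classes=num_classes, input_size=32, filters=8, depth=1,
        mpst_grids=(8, 4), token_dim=16, cycles_per_branch=1,
        swin=SwinBlockConfig(window=4, shift=2, heads=2, mlp_dim=16,
                             dropout_rate=0.0),
        variant=variant, seed=seed)


@pytest.fixture
def tiny_image_set(rng) -> ImageSet:
    """30 random 32-pixel images across 3 classes (10 each)."""
    images = rng.random((30, 32, 32, 3)).astype(np.float32)
    labels = np.repeat(np.arange(3), 10)
    return ImageSet(images, labels, ["a", "b", "c"])


@pytest.fixture(scope="session")
def easy3_dataset():
    """Well-separated 3-class synthetic set rendered at the desk input size."""
    spec = sm.preset_spec("easy3", images_per_class=40, image_size=112, seed=7)
    ds = sm.make_dataset(spec)
    return ImageSet(ds.images, ds.labels, ds.class_names)
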