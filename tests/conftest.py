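import numpy as np
import pytest

from cishquant.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """A default 256x256 clean scene with ground truth (no blur/noise)."""
    spec = SceneSpec(seed=11)
    image, gt = generate_scene(spec)
    return spec, image, gt


def small_scene_base():
    """Scene conditions for fast tests: 2 gate-sized nuclei on a 96px tile."""
    from dataclasses import replace

    from cishquant.workflows import TRAINING_SCENE

    return replace(
        TRAINING_SCENE,
        image_height_px=96,
        image_width_px=96,
        n_nuclei=2,
        nucleus_radius_range_px=(13, 17),
    )


@pytest.fixture(scope="session", name="small_scene_base")
def small_scene_base_fixture():
    return small_scene_base()


@pytest.fixture(scope="session")
def tiny_trained_model(small_scene_base):
    """A small U-net overfitted on a few 96x96 tiles; for plumbing tests."""
    from cishquant import segmentation as seg
    from cishquant.workflows import make_training_set

    images, labels = make_training_set(6, seed=5, base=small_scene_base)
    config = seg.TrainConfig(epochs=30, depth=2, base_filters=8, seed=5, learning_rate=3e-4)
    model = seg.build_model(config)
    seg.train(model, images, labels, config)
    return model
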