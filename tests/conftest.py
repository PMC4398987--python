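import numpy as np
import pytest

from wildtrack.pipeline import PipelineConfig, train_model_from_images
from wildtrack.synthetic import SceneSpec, generate_sequence, generate_training_images


def synth_config() -> PipelineConfig:
    """Pipeline settings for the 320x180 synthetic working resolution."""
    return PipelineConfig(scale=1.0, spatial_bandwidth=4.0, min_segment_size=40)


@pytest.fixture(scope="session")
def scene_spec() -> SceneSpec:
    return SceneSpec()


@pytest.fixture(scope="session")
def trained_model(scene_spec):
    """Color model trained once on generated annotated images."""
    pairs = generate_training_images(scene_spec, seed=11)
    return train_model_from_images(pairs, synth_config(), seed=0)


@pytest.fixture(scope="session")
def sequence(scene_spec):
    """One standard synthetic scene (3 blobs, clutter, pan, occlusion)."""
    return generate_sequence(scene_spec, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
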