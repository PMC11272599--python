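import numpy as np
import pytest

from shockscale.net import ModelConfig
from shockscale.synth_ecg import CLASS_LABELS, SynthConfig, generate_dataset
from shockscale.train_eval import ImageSet, build_image_set


@pytest.fixture(scope="session")
def small_fragments():
    """40 clean-ish fragments (10 per class) shared across fast tests."""
    cfg = SynthConfig(seed=5, noise_sd=0.05)
    return generate_dataset({c: 10 for c in CLASS_LABELS}, cfg)


@pytest.fixture(scope="session")
def small_images(small_fragments) -> ImageSet:
    """32x32 scalograms of the small fragment set."""
    return build_image_set(small_fragments, size=32)


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ModelConfig:
    """A miniature architecture for fast training-mechanics tests."""
    return ModelConfig(
        input_size=32, conv_filters=(4, 4, 8, 8, 8), gru_units=8, dense_units=8
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
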