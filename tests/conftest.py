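import numpy as np
import pytest

from patchseg.model import NetworkSpec, TrainConfig
from patchseg.phantom import Distractor, PhantomConfig, generate_phantom
from patchseg.volume import LabelMap, MpVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small phantom grid that keeps unit tests fast."""
    return PhantomConfig(
        grid_shape=(32, 32, 8), spacing=(2.0, 2.0, 5.0), tumour_radius=8.0, seed=11
    )


@pytest.fixture
def small_phantom(small_config):
    return generate_phantom(small_config)


@pytest.fixture
def distractor_config(small_config):
    from dataclasses import replace

    return replace(
        small_config,
        distractors=(Distractor(centre=(14.0, 14.0, 17.5), radius=6.0),),
    )


@pytest.fixture
def tiny_spec():
    """Scaled-down network spec (same 9-layer structure) for fast training."""
    return NetworkSpec(conv_filters=(4, 8, 16, 32), fc_width=32)


@pytest.fixture
def fast_train_config():
    return TrainConfig(lr=1.0, batch_size=64, max_epochs=5, seed=0)


def make_volume(arrays=None, shape=(12, 12, 4), spacing=(1.0, 1.0, 1.0), seed=0):
    rng = np.random.default_rng(seed)
    if arrays is None:
        arrays = [rng.standard_normal(shape) for _ in range(3)]
    return MpVolume(
        t2w=arrays[0], dwi_b0=arrays[1], dwi_high_b=arrays[2], spacing=spacing
    )
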