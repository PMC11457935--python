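import numpy as np
import pytest
from hypothesis import settings

from embgan.network import Critic, CriticConfig, Segmentor, SegmentorConfig

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_segmentor():
    return Segmentor(SegmentorConfig(n_levels=2, base_channels=4), seed=1)


@pytest.fixture(scope="session")
def tiny_critic():
    return Critic(CriticConfig(n_levels=2, base_channels=4, global_conv_k=5), seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
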