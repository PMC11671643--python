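import numpy as np
import pytest

from sssdiff import DenoiserConfig, SimplexSpec, make_linear_schedule


@pytest.fixture(scope="session")
def paper_schedule():
    """The standard linear schedule: T=1000, beta 1e-4 -> 0.02."""
    return make_linear_schedule(1000, 1e-4, 0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest buildable UNet, with attention, for structural/gradient tests."""
    return DenoiserConfig(image_size=8, base_channels=4,
                          channel_multipliers=(1, 2), res_blocks_per_level=1,
                          attention_resolutions=frozenset({4}), attention_heads=2)


@pytest.fixture(scope="session")
def mini_cfg():
    """The desk-scale training profile config."""
    return DenoiserConfig(image_size=64, base_channels=16,
                          channel_multipliers=(1, 2, 2), res_blocks_per_level=1,
                          attention_resolutions=frozenset({16}), attention_heads=2)


@pytest.fixture(scope="session")
def default_simplex():
    return SimplexSpec(base_frequency=2 ** -6, octaves=6, decay=0.8, seed=0)
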