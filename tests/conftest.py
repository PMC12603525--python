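import numpy as np
import pytest

from synmap import ChannelConfig, DetectionParams, SynthConfig, generate_field


@pytest.fixture(scope="session")
def medium_field():
    """A 32x32 µm single-channel field (~50 puncta) with its ground truth."""
    cfg = SynthConfig(
        field_size_um=(32.0, 32.0),
        channels=[
            ChannelConfig("SV2A", density_per_100um2=5.0,
                          amplitude_mean=386.0, amplitude_sd=58.0)
        ],
        seed=7,
    )
    images, truth = generate_field(cfg)
    return cfg, images[0], truth


@pytest.fixture
def default_params():
    return DetectionParams(quality_threshold=45.0, exclude_border=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
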