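import numpy as np
import pytest

from neurofatigue.synth import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_config():
    """10-minute clean-generator config used by fast recovery checks."""
    return SimulationConfig(
        lecture_duration=600.0,
        blink_rate=0.0,
        line_noise_amp=0.0,
        seed=7,
    )


@pytest.fixture
def fs():
    return 512.0
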