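import numpy as np
import pytest

from ocuclean import PipelineConfig, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast pipeline tests: 8 channels
    (7 EEG + 1 EOG), 60 epochs of 2 s at 250 Hz (500 samples, the shortest
    epoch supporting the full 5-level decomposition)."""
    cfg = PipelineConfig(seed=7)
    cfg.data.n_channels = 8
    cfg.data.n_eog = 1
    cfg.data.n_epochs = 60
    cfg.data.duration = 2.0
    cfg.features.n_components = 20
    return cfg


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return make_fixture(small_config)
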