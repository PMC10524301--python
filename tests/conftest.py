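import numpy as np
import pytest

import tectovis.synthetic as syn


@pytest.fixture
def small_config():
    """Noiseless ground truth on a small grid for fast exact checks."""
    return syn.GroundTruthConfig(shape=(48, 48), sigma_noise=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
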