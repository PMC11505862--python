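import numpy as np
import pytest

from emgpac.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """3+3 subjects, 6 s, 2 channels/muscle: fast end-to-end material."""
    cfg = SimConfig(n_cases=3, n_controls=3, duration_s=6.0,
                    channels_per_muscle=2, bad_channel_rate=0.0, seed=11)
    recordings, manifest = generate_cohort(cfg)
    return cfg, recordings, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
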