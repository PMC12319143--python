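import numpy as np
import pytest
from hypothesis import settings

from reachstop import StudyConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A scaled-down study: quick to simulate, same structure as the default."""
    return StudyConfig(n_participants=4, n_vr_trials=40, sst_n_trials=80,
                       rng_seed=7)


@pytest.fixture
def flat_participant():
    """Participant latents with round numbers, handy for analytic checks."""
    return {
        "it_choc": 300.0, "it_neutral": 300.0,
        "t_reach_choc": 512.0, "t_reach_neutral": 507.0,
        "tts_choc": 247.0, "tts_neutral": 260.0,
        "dwell_first_choc": 396.0, "dwell_first_neutral": 289.0,
        "dwell_total_choc": 677.0, "dwell_total_neutral": 461.0,
    }
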