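import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from earpipe.model import SplitPlan
from earpipe.synthdata import NoiseConfig, ProtocolConfig, generate_study


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    """Reduced trial count; everything else at the study defaults."""
    return ProtocolConfig(trials_per_activity=2)


@pytest.fixture(scope="session")
def small_study(small_protocol):
    """Three short sessions at the default noise conditions."""
    return generate_study(small_protocol, NoiseConfig(), seeds=[101, 202, 303])


@pytest.fixture(scope="session")
def split_plan():
    return SplitPlan(train_sessions=["S1", "S2"], test_session="S3", rng_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def quiet_noise():
    """No EMG, no line noise: pure EEG background + wander."""
    cfg = ProtocolConfig(trials_per_activity=1)
    noise = dataclasses.replace(
        NoiseConfig(),
        emg_gain_matrix=np.zeros((cfg.n_activities, 16)),
        line_baseline_amplitude=0.0,
        line_burst_amplitude=0.0,
    )
    return cfg, noise
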