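import matplotlib
import numpy as np
import pytest
from hypothesis import settings

from ppgram import SimulationParams, simulate_ppg

matplotlib.use("Agg")

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_80bpm_5min():
    """Artifact-free constant-80-bpm synthetic PPG, 5 minutes at 64 Hz."""
    params = SimulationParams(duration=300.0, hr_bpm=80.0, hrv_sd=0.0,
                              noise_sd=0.0, artifact_rate=0.0, seed=1)
    return simulate_ppg(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
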