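import numpy as np
import pytest

from eegtopo import (
    Recording,
    SimulationConfig,
    make_montage,
    make_templates,
    simulate_microstate_eeg,
)


@pytest.fixture(scope="session")
def montage19():
    return make_montage(19, seed=11)


@pytest.fixture(scope="session")
def templates4(montage19):
    return make_templates(montage19, 4, seed=12)


@pytest.fixture(scope="session")
def small_sim(montage19, templates4):
    """1000-frame microstate recording with ground truth."""
    cfg = SimulationConfig(seed=21, n_timeframes=1000)
    rec, truth = simulate_microstate_eeg(cfg, montage19, templates4)
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def random_recording(rng):
    return Recording(data=rng.normal(size=(16, 200)), sampling_rate=250.0)
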