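import numpy as np
import pytest

from dispvep.synth import SimConfig, SourceSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim():
    """A small noiseless dataset for structural checks."""
    # 5 s = 7 F1 cycles and exactly 100 F2 cycles, so both fundamentals are
    # bin-aligned in the epoch spectrum
    cfg = SimConfig(
        n_subjects=2, n_trials_per_condition=2, n_channels=8,
        noise_amplitude=0.0, sensor_noise_amplitude=0.0, subject_gain_sd=0.0,
        active_duration=5.0, seed=0,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def grating_task_dataset():
    """20-subject grating dataset with the attention effect planted at
    184 ms, at default signal/noise amplitudes (reduced channel/trial
    counts keep it desk-scale)."""
    cfg = SimConfig(
        n_subjects=20, n_trials_per_condition=15, n_channels=16,
        conditions=("grating:attend_fixation", "grating:attend_stimulus"),
        seed=11,
    )
    return cfg, simulate_dataset(cfg)
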