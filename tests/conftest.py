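import numpy as np
import pytest

from minf.eeg_pipeline import Recording
from minf.synthetic_data import CohortSimConfig, EEGSimConfig, generate_eeg_session


@pytest.fixture(scope="session")
def small_cfg() -> EEGSimConfig:
    """A compact session: few channels/trials, study-scale ERD and SNR."""
    return EEGSimConfig(n_channels=8, n_trials_per_class=8, erd_depth=0.5,
                        snr=2.0, seed=11)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_eeg_session(small_cfg)


@pytest.fixture(scope="session")
def small_session_sources(small_cfg):
    return generate_eeg_session(small_cfg, return_sources=True)


@pytest.fixture()
def sine_recording():
    """Single-channel pure-tone factory for filter tests."""

    def make(freq: float, fs: float = 500.0, dur: float = 10.0, amp: float = 1.0,
             dc: float = 0.0, n_channels: int = 1) -> Recording:
        t = np.arange(int(dur * fs)) / fs
        sig = amp * np.sin(2 * np.pi * freq * t) + dc
        return Recording(np.tile(sig, (n_channels, 1)), fs,
                         [f"ch{i}" for i in range(n_channels)])

    return make


@pytest.fixture(scope="session")
def null_cohort_cfg():
    return CohortSimConfig(n_subjects=21, seed=101)
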