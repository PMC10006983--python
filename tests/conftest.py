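import numpy as np
import pytest

from ssvepid.data import Trial, TrialSet
from ssvepid.preprocessing import default_filterbank
from ssvepid.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_simconfig() -> SimConfig:
    """Small, easy identification problem: 4 subjects, 3 blocks, 10 dB SNR."""
    return SimConfig(
        n_subjects=4,
        n_blocks=3,
        stim_frequencies_hz=(10.0,),
        fs_hz=250.0,
        trial_duration_s=2.0,
        n_channels=6,
        snr_db=10.0,
        subject_separation=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_trialset(small_simconfig) -> TrialSet:
    return simulate_dataset(small_simconfig)


@pytest.fixture(scope="session")
def two_band_bank():
    return default_filterbank(8.0, 30.0, n_bands=2)


def sinusoid_trial(
    freq_hz: float,
    fs_hz: float = 250.0,
    duration_s: float = 4.0,
    n_channels: int = 2,
    amplitude: float = 1.0,
    subject_id: int = 1,
) -> Trial:
    """A multichannel pure sinusoid (each row identical), for filter oracles."""
    t = np.arange(int(round(fs_hz * duration_s))) / fs_hz
    row = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return Trial(
        data=np.tile(row, (n_channels, 1)),
        fs_hz=fs_hz,
        subject_id=subject_id,
        block_index=1,
        stim_freq_hz=freq_hz,
        channel_names=[f"CH{i+1}" for i in range(n_channels)],
    )


def random_spd(rng: np.random.Generator, n: int, jitter: float = 1e-3) -> np.ndarray:
    """Random symmetric positive-definite matrix, trace-normalized."""
    a = rng.standard_normal((n, 2 * n))
    c = a @ a.T / (2 * n) + jitter * np.eye(n)
    return c / np.trace(c)
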