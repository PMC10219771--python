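import numpy as np
import pytest

from runcoord import emg, gait
from runcoord.signal_io import ChannelKind, Side
from runcoord.synth import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def jitter_cfg() -> SimulationConfig:
    """A short session with mild, realistic cycle-to-cycle variability."""
    return SimulationConfig(
        duration_s=18.0, sigma_amp=0.05, sigma_time=0.02, seed=7
    )


@pytest.fixture(scope="session")
def jitter_session(jitter_cfg):
    return simulate_session(jitter_cfg)


@pytest.fixture(scope="session")
def clean_cfg() -> SimulationConfig:
    """Zero cycle-to-cycle variability: every cycle repeats the template."""
    return SimulationConfig(duration_s=18.0, seed=11)


@pytest.fixture(scope="session")
def clean_session(clean_cfg):
    return simulate_session(clean_cfg)


@pytest.fixture(scope="session")
def clean_analysis(clean_session):
    """Preprocessed recording + per-side partitions of the clean session."""
    rec, gt = clean_session
    pre = emg.preprocess_emg(rec)
    parts = {
        side: gait.segment_gait(
            pre.gyro(side, ChannelKind.GYRO_X), n_cycles=20, side=side
        )
        for side in (Side.LEFT, Side.RIGHT)
    }
    return pre, parts, gt


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
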