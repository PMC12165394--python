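import numpy as np
import pytest

from pdgait.io_model import AnalysisConfig
from pdgait.synthetic_data import (
    TUGSimParams,
    WalkSimParams,
    simulate_tug_trajectory,
    simulate_walking_trial,
)


@pytest.fixture()
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tug_trial_clean():
    """Noise-free TUG trial with ground-truth events (seed 7)."""
    return simulate_tug_trajectory(TUGSimParams(seed=7))


@pytest.fixture(scope="session")
def walk_trial_clean():
    """Noise-free walking trial with ground-truth panel (seed 3)."""
    return simulate_walking_trial(WalkSimParams(seed=3))


@pytest.fixture(scope="session")
def walk_trial_noisy():
    """Walking trial with 2 mm marker noise and known truth."""
    return simulate_walking_trial(
        WalkSimParams(toe_clearance=0.034, noise_sd_m=0.001, seed=11)
    )


def match_events(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Absolute error of each detected event against its nearest truth event."""
    return np.array([np.min(np.abs(truth - d)) for d in detected])
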