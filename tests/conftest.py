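import warnings

import numpy as np
import pytest

from torpormeter import SyntheticConfig, simulate_baseline_day, simulate_cohort


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # short-chain fits in the tests deliberately trade R-hat polish for speed
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="R-hat above")
        warnings.filterwarnings("ignore", message="posterior mass")
        yield


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale grid (30-min bins) for fast model tests."""
    return SyntheticConfig(seed=7, K=48, bin_width=30, D=3, sigma1=(0.3, 0.2))


@pytest.fixture(scope="session")
def baseline_recording(small_config):
    return simulate_baseline_day(small_config, animal=0)


@pytest.fixture(scope="session")
def cohort_small():
    """Two animals at two ambient temperatures with deep scheduled bouts."""
    cfg = SyntheticConfig(seed=3, n_animals=2, ta_grid=(12.0, 24.0))
    recordings, masks = simulate_cohort(cfg)
    return cfg, recordings, masks


def rng(seed=0):
    return np.random.default_rng(seed)
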