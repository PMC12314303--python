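import numpy as np
import pytest

from streamsync.io_core import AnalysisConfig
from streamsync.synthetic_data import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_session():
    """A small quiet session (no effects) shared across read-only tests."""
    cfg = SimulationConfig(
        n_trials_per_condition=10, block_size=5,
        channels_per_region={"IPL": 2, "VTC": 2, "HIP": 1},
        spike_rate_per_min=0.5,
    )
    rec, events, gt = simulate_session(cfg, seed=1234)
    return cfg, rec, events, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
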