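import numpy as np
import pandas as pd
import pytest

from anglesel import morpho, synth
from anglesel.config import RunConfig, SimConfig


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A reduced pond experiment for fast end-to-end tests."""
    return SimConfig(seed=2, n_per_pond=10, obs_days=3, angling_days=7)


@pytest.fixture(scope="session")
def small_run_cfg(small_cfg) -> RunConfig:
    return RunConfig(seed=2, simulate=small_cfg, horizons=(7,))


@pytest.fixture(scope="session")
def pop200():
    """200 simulated fish with landmarks and their GPA (shared across tests)."""
    cfg = SimConfig(seed=3, n_ponds=5)
    ind = synth.simulate_individuals(cfg)
    lms = synth.simulate_landmarks(ind, cfg)
    gpa = morpho.generalized_procrustes(lms)
    return cfg, ind, lms, gpa


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_detections(seconds, antenna="distant_spot", fish="F001", base="2014-06-01"):
    """Helper: detection frame from raw second offsets."""
    ts = pd.Timestamp(base) + pd.to_timedelta(list(seconds), unit="s")
    return pd.DataFrame({"fish_id": fish, "antenna": antenna, "timestamp": ts})
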