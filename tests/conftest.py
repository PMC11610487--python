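import numpy as np
import pytest

from waspclock.core_io import TimeDesign, default_designs
from waspclock.synthdata import SimulationConfig, simulate


@pytest.fixture(scope="session")
def designs():
    return default_designs()


@pytest.fixture(scope="session")
def dd_design(designs):
    return designs["DD"]


@pytest.fixture(scope="session")
def times(dd_design):
    return np.asarray(dd_design.times)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated study shared across tests (read-only)."""
    cfg = SimulationConfig(n_transcripts=600, seed=42)
    dd, ll, truth = simulate(cfg)
    return cfg, dd, ll, truth


def circular_diff(a, b, period=24.0):
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), period)
    return np.minimum(d, period - d)
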