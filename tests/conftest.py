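"""Shared fixtures: seeded synthetic deployments at test-friendly sizes."""

import numpy as np
import pandas as pd
import pytest

from seamspc import ScenarioConfig, align_streams, generate_scenario
from seamspc.synthetic import default_blocks, default_redundancy_groups


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_scenario():
    """One month of the default deployment, hourly grid after alignment."""
    config = ScenarioConfig(start="2015-05-16", end="2015-06-16", seed=7)
    streams, truth = generate_scenario(config)
    table = align_streams(streams, grid_step="1h", max_gap="6h")
    return streams, truth, table


@pytest.fixture(scope="session")
def complete_table():
    """Six gap-free weeks (no missingness) for exact-identity tests."""
    config = ScenarioConfig(start="2015-05-16", end="2015-06-27", seed=3,
                            missing_rate=0.0, outage_rate=0.0)
    streams, _ = generate_scenario(config)
    return align_streams(streams, grid_step="1h", max_gap="6h")


@pytest.fixture(scope="session")
def stationary_tables():
    """In-control deployment (no seasonal trend) split into two halves.

    Both halves come from the same stationary process, so the second half
    should look 'inside' to a model calibrated on the first.
    """
    config = ScenarioConfig(start="2015-05-16", end="2015-07-16", seed=11,
                            trend_amplitude=0.0, missing_rate=0.0,
                            outage_rate=0.0)
    streams, truth = generate_scenario(config)
    table = align_streams(streams, grid_step="1h", max_gap="6h")
    cal = table.window(None, "2015-06-16")
    mon = table.window("2015-06-16", None)
    return cal, mon, truth


@pytest.fixture(scope="session")
def blocks():
    return default_blocks()


@pytest.fixture(scope="session")
def redundancy_groups():
    return default_redundancy_groups()


@pytest.fixture
def random_complete(rng):
    """Factory for small complete random matrices as DataFrames."""
    def make(n=20, p=6, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        return pd.DataFrame(local.standard_normal((n, p)),
                            columns=[f"v{j}" for j in range(p)])
    return make
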