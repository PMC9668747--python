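"""Shared synthetic fixtures.

Everything is generated programmatically at fixed seeds; the heavier
session-scale objects are session-scoped so the whole suite pays for them
once.
"""

import numpy as np
import pytest

import plateaulearn as pl


@pytest.fixture(scope="session")
def behavior_a():
    """Default 60-lap environment-A session."""
    return pl.generate_behavior(60, "A", seed=11)


@pytest.fixture(scope="session")
def ca1_session(behavior_a):
    """Default-noise CA1 population with ground truth, dF/F and maps."""
    traces, truth = pl.generate_ca1_traces(behavior_a, n_cells=120,
                                           frac_place=0.4, seed=12)
    traces = pl.compute_dff(traces)
    maps = pl.build_activity_map(traces, behavior_a)
    return traces, truth, maps


@pytest.fixture(scope="session")
def ca1_records(ca1_session, behavior_a):
    traces, truth, maps = ca1_session
    records = pl.classify_place_cells(maps, traces, behavior_a, seed=13)
    return records, truth


@pytest.fixture(scope="session")
def uniform_population():
    """Homogeneous chain population at the stock configuration."""
    cfg = pl.build_config("uniform")
    return pl.simulate_chains(cfg, seed=21)


@pytest.fixture(scope="session")
def small_population():
    """Small uniform population for cheap plateau-model tests."""
    cfg = pl.build_config("uniform", overrides={"n_chains": 200})
    return pl.simulate_chains(cfg, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
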