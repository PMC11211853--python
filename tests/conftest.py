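"""Shared fixtures: a simulated proteome/database and signal spectra.

The database build (digestion + modification enumeration + decoys for a
50-protein proteome) is the expensive step, so it is session-scoped and
shared across the integration and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from lectern.digest import build_database
from lectern.simulate import SimulationParams, simulate_proteome, simulate_spectra


@pytest.fixture(scope="session")
def sim_params() -> SimulationParams:
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def sim_records(sim_params):
    return simulate_proteome(sim_params)


@pytest.fixture(scope="session")
def sim_db(sim_records):
    return build_database(sim_records, decoy_seed=1)


@pytest.fixture(scope="session")
def signal_spectra(sim_records, sim_params):
    """200 spectra at fragment coverage 0.9, 5 ppm jitter, 20 noise peaks."""
    return simulate_spectra(sim_records, sim_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
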