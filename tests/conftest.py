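"""Shared fixtures.

The heavy session fixture (`nine_topology_fits`) runs the full
model-selection experiment once — synthetic depletion + recovery data from
the calibrated consensus-network ground truth, then 200-start fits of all
nine autoregulation topologies — and is shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import duonet as dn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: seeds of the shared model-selection experiment
STUDY_DATA_SEED = 11
STUDY_FIT_SEED = 7


@pytest.fixture(scope="session")
def ground_truth():
    """Calibrated consensus-network (topology, parameters) pair."""
    return dn.default_ground_truth()


@pytest.fixture(scope="session")
def noise_free_data():
    """Deterministic study datasets (no measurement noise, one replicate)."""
    config = dn.GeneratorConfig(noise_cv=0.0, n_replicates=1, seed=0)
    return dn.generate_study(config)


@pytest.fixture(scope="session")
def study_config():
    """The study-condition generator: noise CV 0.1, 3 replicates, fixed seed."""
    return dn.GeneratorConfig(noise_cv=0.1, n_replicates=3, seed=STUDY_DATA_SEED)


@pytest.fixture(scope="session")
def study_data(study_config):
    return dn.generate_study(study_config)


@pytest.fixture(scope="session")
def nine_topology_fits(study_data):
    """Leaderboard and fits of the nine autoregulation topologies."""
    leaderboard, fits = dn.rank_topologies(
        study_data, n_starts=200, seed=STUDY_FIT_SEED, tolerance_factor=2.0
    )
    return leaderboard, fits


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
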