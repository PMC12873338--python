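"""Shared fixtures.

The desk-profile study fixtures (simulated training set, trained NPE and
posterior-mean networks) are session-scoped because they are expensive;
all inference-level tests share one trained bundle.
"""

from __future__ import annotations

import numpy as np
import pytest

from pillarwalk import ModelParameters, build_pillar_forest, gaussian_gradient
from pillarwalk.cpm import SimulationConfig
from pillarwalk.npe import TrainConfig, train_joint, train_posterior_mean
from pillarwalk.study import StudySetup


@pytest.fixture(scope="session")
def desk_setup() -> StudySetup:
    return StudySetup.desk()


@pytest.fixture(scope="session")
def tiny_geometry():
    """A very small arena for fast simulator-level tests."""
    return build_pillar_forest(2, 2, pillar_diameter_um=5.0, gap_um=10.0,
                               clearing_um=12.0)


@pytest.fixture(scope="session")
def tiny_field(tiny_geometry):
    return gaussian_gradient(tiny_geometry)


@pytest.fixture()
def tiny_sim_config():
    return SimulationConfig(n_cells=4, total_time_s=120.0, dt_obs_s=30.0,
                            burn_in_mcs=50)


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return ModelParameters(2.0, 1.0, float(np.log10(2.1e-3)),
                           float(np.log10(41.73)))


# ---------------------------------------------------------------------------
# expensive shared study bundle (desk profile)
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def desk_pairs(desk_setup):
    rng = np.random.default_rng(2024)
    train = desk_setup.generate_pairs(2000, rng)
    val = desk_setup.generate_pairs(100, rng)
    return train, val


@pytest.fixture(scope="session")
def desk_train_config():
    return TrainConfig(max_epochs=24, patience=5)


@pytest.fixture(scope="session")
def desk_npe(desk_pairs, desk_train_config):
    train, val = desk_pairs
    return train_joint(train, val, desk_train_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def desk_pm(desk_pairs, desk_train_config):
    train, val = desk_pairs
    return train_posterior_mean(train, val, desk_train_config,
                                np.random.default_rng(8))
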