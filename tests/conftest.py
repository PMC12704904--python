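"""Shared fixtures.

Expensive artifacts (landscape sweeps, the small cohort) are session-scoped
so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cupball.cohort import CohortConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cupball.dynamics import ControllerSpec, SystemParams
from cupball.landscapes import StrategyGrid, sweep_stability


@pytest.fixture(scope="session")
def medium_params() -> SystemParams:
    return SystemParams(pendulum_length=0.6)


@pytest.fixture(scope="session")
def sweep_ctrl() -> ControllerSpec:
    """Controller used for landscape sweeps: K=40, B=70, A=0.3."""
    return ControllerSpec(40.0, 70.0, 0.3, 0.5)


@pytest.fixture(scope="session")
def small_grid() -> StrategyGrid:
    return StrategyGrid.with_resolution(19, 15)


@pytest.fixture(scope="session")
def medium_stability_map(medium_params, small_grid, sweep_ctrl):
    return sweep_stability(medium_params, small_grid, sweep_ctrl)


@pytest.fixture(scope="session")
def small_cohort():
    """3 participants x 2 protocols x 3 pendulums x 3 trials = 54 trials."""
    cfg = CohortConfig(n_participants=3, trials_per_condition=3, master_seed=1)
    records, manifest = generate_cohort(cfg)
    return cfg, records, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
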