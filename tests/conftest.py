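"""Shared fixtures.

The expensive simulations (duction sweeps, the saccade) are session-scoped
so the acceptance checks and the behavioural unit tests share one run each.
"""

import numpy as np
import pytest

from oculoplant.anatomy import make_default_anatomy
from oculoplant.experiments import run_duction_sweep, run_saccade
from oculoplant.globe_dynamics import Plant, solve_static


@pytest.fixture(scope="session")
def default_config():
    return make_default_anatomy()


@pytest.fixture(scope="session")
def plant(default_config):
    return Plant(default_config)


@pytest.fixture(scope="session")
def central_solution(default_config, plant):
    return solve_static(default_config, (0.0, 0.0), plant=plant)


@pytest.fixture(scope="session")
def vertical_sweep(default_config, plant):
    """30 deg supraduction, central gaze, 30 deg infraduction fixations."""
    return run_duction_sweep(
        default_config, "vertical", [-30.0, 0.0, 30.0], plant=plant,
        keep_states=True,
    )


@pytest.fixture(scope="session")
def horizontal_sweep(default_config, plant):
    """13-gaze horizontal sweep from 30 deg adduction to 30 deg abduction."""
    angles = [float(a) for a in np.arange(-30, 31, 5)]
    return run_duction_sweep(default_config, "horizontal", angles, plant=plant)


@pytest.fixture(scope="session")
def saccade_result(default_config, plant):
    """30 deg abducting saccade from central gaze."""
    return run_saccade(
        default_config, (0.0, 0.0), (30.0, 0.0), duration=0.2, plant=plant,
        settle_time=0.4,
    )
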