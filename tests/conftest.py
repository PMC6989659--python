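"""Shared fixtures: synthetic trajectories and speed series.

Heavier fixtures are session-scoped so recovery tests across modules
reuse one simulated foraging trajectory.
"""

import numpy as np
import pytest

from speedcells import kinematics as kin
from speedcells import synthetic_session as ss

SEED = 7


@pytest.fixture(scope="session")
def trajectory_short():
    """120-s foraging trajectory (fast tests)."""
    return ss.simulate_trajectory(ss.TrajectoryModel(), 120.0, seed=SEED)


@pytest.fixture(scope="session")
def trajectory_long():
    """20-minute foraging trajectory (recovery tests)."""
    return ss.simulate_trajectory(ss.TrajectoryModel(), 1200.0, seed=SEED)


def speed_from_trajectory(traj):
    x_raw, y_raw = kin.interpolate_position(traj)
    x = kin.smooth_position(x_raw)
    y = kin.smooth_position(y_raw)
    return kin.compute_speed(x, y)


@pytest.fixture(scope="session")
def speed_short(trajectory_short):
    return speed_from_trajectory(trajectory_short)


@pytest.fixture(scope="session")
def speed_long(trajectory_long):
    return speed_from_trajectory(trajectory_long)


@pytest.fixture(scope="session")
def covariates_long(trajectory_long):
    return ss.fine_covariates(trajectory_long, None, 1200.0)


def straight_trajectory(speed_cms=10.0, duration=60.0, frame_rate=30.0, heading=0.0):
    """Constant-velocity two-LED trajectory along ``heading``."""
    n = int(duration * frame_rate) + 1
    ts = np.arange(n) / frame_rate
    d = np.array([np.cos(heading), np.sin(heading)])
    front = 20.0 + speed_cms * ts[:, None] * d
    rear = front - 12.0 * d
    from speedcells.session_io import TrajectoryRaw

    return TrajectoryRaw(ts, front, rear, np.zeros(n, dtype=bool))
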