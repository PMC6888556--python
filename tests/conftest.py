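import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mobexpo.pollution import Grid1km  # noqa: E402
from mobexpo.synthetic import generate_world  # noqa: E402
from mobexpo.trajectory_io import Trajectory, TrajectoryRecord  # noqa: E402


def make_traj(points, user_id="u1", event_type="regular_update"):
    """Build a trajectory from (day, t_seconds, x, y) tuples."""
    return Trajectory(
        user_id=user_id,
        records=[TrajectoryRecord(user_id=user_id, day=d, t=t, x=x, y=y,
                                  event_type=event_type)
                 for d, t, x, y in points],
    )


@pytest.fixture(scope="session")
def small_grid():
    return Grid1km(x0=0.0, y0=0.0, n_rows=20, n_cols=20)


@pytest.fixture(scope="session")
def small_world(small_grid):
    """Compact seeded world reused by slower integration tests."""
    return generate_world(seed=7, n_agents=30, n_clusters=2, days=1,
                          grid=small_grid, n_pm_stations=30, n_met_stations=49)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
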