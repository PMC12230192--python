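import datetime as dt

import numpy as np
import pandas as pd
import pytest

from gibmove import (ClusterPhase, SimConfig, Trajectory,
                     simulate_levy_trajectory)
from gibmove.trajectory_io import IST


def make_trajectory(timestamps, lons, lats, source="GPS",
                    animal_id="TEST") -> Trajectory:
    """Build a Trajectory directly from parallel lists."""
    fixes = pd.DataFrame({
        "timestamp": pd.DatetimeIndex(timestamps),
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
        "source": source,
    })
    return Trajectory(animal_id=animal_id, fixes=fixes)


def hourly_timestamps(start: dt.datetime, n: int, step_hours: float = 2.0):
    if start.tzinfo is None:
        start = start.replace(tzinfo=IST)
    return [start + dt.timedelta(hours=step_hours * i) for i in range(n)]


@pytest.fixture(scope="session")
def two_phase_config() -> SimConfig:
    """Two 5-day stationary phases 30 km apart, one transit day between:
    ground truth for the sequential clustering stage (35 fixes/phase)."""
    return SimConfig(
        seed=11,
        start_date=dt.date(2015, 6, 1),
        end_date=dt.date(2015, 6, 11),
        cluster_phases=(
            ClusterPhase(dt.date(2015, 6, 1), 5, (0.0, 0.0)),
            ClusterPhase(dt.date(2015, 6, 7), 5, (30000.0, 0.0)),
        ),
    )


@pytest.fixture(scope="session")
def two_phase_traj(two_phase_config):
    return simulate_levy_trajectory(two_phase_config)


@pytest.fixture(scope="session")
def year_traj():
    """A study-length (multi-season) simulated trajectory."""
    return simulate_levy_trajectory(SimConfig(
        seed=5, start_date=dt.date(2015, 4, 15),
        end_date=dt.date(2016, 5, 28)))
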