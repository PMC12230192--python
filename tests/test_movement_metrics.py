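import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from gibmove import (count_line_crossings, daily_summaries, hourly_rate,
                     seasonal_summaries, step_series, turning_histogram)
from gibmove.movement_metrics import StepSeries
from gibmove.trajectory_io import IST

from conftest import hourly_timestamps, make_trajectory


def make_steps(lengths_m, date=dt.date(2015, 4, 1), season="summer",
               duration_h=2.0):
    n = len(lengths_m)
    start = [dt.datetime.combine(date, dt.time(5, 30), tzinfo=IST)
             + dt.timedelta(hours=duration_h * i) for i in range(n)]
    df = pd.DataFrame({
        "start_time": pd.DatetimeIndex(start),
        "end_time": pd.DatetimeIndex(start)
        + pd.Timedelta(hours=duration_h),
        "length_m": np.asarray(lengths_m, dtype=float),
        "duration_h": duration_h,
        "bearing_deg": 90.0,
        "season": season,
        "date": date,
        "turning_angle_deg": [np.nan] + [0.0] * (n - 1),
    })
    return StepSeries(steps=df)


class TestStepSeries:
    def test_zero_length_for_identical_coordinates(self):
        ts = hourly_timestamps(dt.datetime(2015, 4, 1, 5, 30), 2)
        traj = make_trajectory(ts, [75.9, 75.9], [17.8, 17.8])
        steps = step_series(traj)
        assert steps.steps["length_m"].iloc[0] == 0.0

    def test_equatorial_degree_matches_ellipsoid(self):
        ts = hourly_timestamps(dt.datetime(2015, 4, 1, 5, 30), 2)
        traj = make_trajectory(ts, [0.0, 1.0], [0.0, 0.0])
        steps = step_series(traj)
        assert steps.steps["length_m"].iloc[0] == pytest.approx(
            111319.49, abs=1.0)

    def test_collinear_eastward_turning_angle_zero(self):
        ts = hourly_timestamps(dt.datetime(2015, 4, 1, 5, 30), 3)
        traj = make_trajectory(ts, [75.90, 75.91, 75.92],
                               [17.80, 17.80, 17.80])
        steps = step_series(traj)
        assert np.isnan(steps.steps["turning_angle_deg"].iloc[0])
        assert steps.steps["turning_angle_deg"].iloc[1] == pytest.approx(
            0.0, abs=1e-3)

    def test_step_count_is_fix_count_minus_one(self, two_phase_traj):
        steps = step_series(two_phase_traj)
        assert len(steps) == len(two_phase_traj) - 1


class TestRatesAndDaily:
    def test_single_step_rate(self):
        steps = make_steps([2000.0], duration_h=2.0)
        assert hourly_rate(steps)["mean_kmh"] == pytest.approx(1.0)

    def test_all_zero_steps(self):
        steps = make_steps([0.0, 0.0, 0.0])
        rates = hourly_rate(steps)
        assert rates["mean_kmh"] == 0.0 and rates["max_kmh"] == 0.0

    def test_daily_sum_is_simple_addition(self):
        steps = make_steps([1000.0, 2000.0, 500.0])
        daily = daily_summaries(steps)
        assert len(daily) == 1
        assert daily["distance_km"].iloc[0] == pytest.approx(3.5)

    def test_conservation_sum_daily_equals_sum_steps(self, year_traj):
        steps = step_series(year_traj)
        daily = daily_summaries(steps)
        assert daily["distance_km"].sum() == pytest.approx(
            steps.total_distance_km, rel=1e-12)

    def test_seasonal_totals_sum_to_grand_total(self, year_traj):
        steps = step_series(year_traj)
        daily = daily_summaries(steps)
        seasonal = seasonal_summaries(daily)
        assert seasonal["total_km"].sum() == pytest.approx(
            daily["distance_km"].sum(), rel=1e-12)

    def test_identical_days_give_identical_season_means(self):
        daily = pd.DataFrame({
            "date": pd.date_range("2015-01-01", periods=365).date,
            "distance_km": 2.0,
            "season": ["winter"] * 59 + ["summer"] * 122 + ["monsoon"] * 92
            + ["post_monsoon"] * 61 + ["winter"] * 31,
        })
        seasonal = seasonal_summaries(daily)
        assert (seasonal["mean_km_per_day"] == 2.0).all()
        assert len(seasonal) == 4


class TestDirectionality:
    def test_straight_line_single_bin_rbar_one(self):
        steps = make_steps([100.0] * 10)  # all turning angles 0
        counts, _, rbar = turning_histogram(steps, n_bins=36)
        assert (counts > 0).sum() == 1
        assert rbar == pytest.approx(1.0)

    def test_counts_conserve_defined_angles(self, two_phase_traj):
        steps = step_series(two_phase_traj)
        counts, _, _ = turning_histogram(steps, n_bins=24)
        n_defined = steps.steps["turning_angle_deg"].notna().sum()
        assert counts.sum() == n_defined

    def test_uniform_angles_small_resultant(self):
        # closed form: under uniformity E[rbar] ~ sqrt(pi)/(2 sqrt(n))
        rng = np.random.default_rng(4)
        n = 10000
        steps = make_steps([100.0] * (n + 1))
        steps.steps.loc[1:, "turning_angle_deg"] = rng.uniform(-180, 180, n)
        _, _, rbar = turning_histogram(steps)
        assert rbar < 0.05

    def test_too_few_bins_rejected(self):
        steps = make_steps([100.0, 100.0])
        with pytest.raises(ValueError):
            turning_histogram(steps, n_bins=1)


def _segments_cross(p1, p2, q1, q2) -> bool:
    """Brute-force segment intersection via orientation tests."""
    def orient(a, b, c):
        v = ((b[0] - a[0]) * (c[1] - a[1])
             - (b[1] - a[1]) * (c[0] - a[0]))
        return 0 if v == 0 else (1 if v > 0 else -1)

    def on_seg(a, b, c):
        return (min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
                and min(a[1], b[1]) <= c[1] <= max(a[1], b[1]))

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True
    return any(o == 0 and on_seg(*pair)
               for o, pair in [(o1, (p1, p2, q1)), (o2, (p1, p2, q2)),
                               (o3, (q1, q2, p1)), (o4, (q1, q2, p2))])


class TestLineCrossings:
    line = LineString([(0.0, 0.0), (10000.0, 0.0)])

    def test_single_crossing(self):
        track = np.array([[5000.0, -100.0], [5000.0, 100.0]])
        assert count_line_crossings(track, [self.line]) == 1

    def test_parallel_one_metre_away(self):
        track = np.array([[0.0, 1.0], [10000.0, 1.0]])
        assert count_line_crossings(track, [self.line]) == 0

    def test_empty_line_set(self):
        track = np.array([[0.0, -1.0], [0.0, 1.0]])
        assert count_line_crossings(track, []) == 0

    def test_zigzag_matches_bruteforce(self):
        # 5 steps alternating across the line
        ys = [-100.0, 100.0, -100.0, 100.0, -100.0, 100.0]
        track = np.column_stack([np.linspace(1000, 9000, 6), ys])
        expected = sum(
            _segments_cross(tuple(track[i]), tuple(track[i + 1]),
                            (0.0, 0.0), (10000.0, 0.0))
            for i in range(5))
        assert expected == 5
        assert count_line_crossings(track, [self.line]) == expected

    def test_distinct_polylines_counted_separately(self):
        other = LineString([(0.0, 10.0), (10000.0, 10.0)])
        track = np.array([[5000.0, -100.0], [5000.0, 100.0]])
        assert count_line_crossings(track, [self.line, other]) == 2
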