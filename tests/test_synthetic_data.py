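import datetime as dt

import numpy as np
import pytest
from scipy import stats

from gibmove import (ClusterPhase, SimConfig, fit_power_law, project,
                     sample_step_lengths, simulate_landscape,
                     simulate_levy_trajectory, step_series,
                     turning_histogram)
from gibmove._geodesy import lonlat_to_utm43n


class TestSimConfigValidation:
    def test_empty_date_range(self):
        with pytest.raises(ValueError, match="date range"):
            SimConfig(start_date=dt.date(2015, 5, 1),
                      end_date=dt.date(2015, 4, 1))

    def test_mu_out_of_range(self):
        with pytest.raises(ValueError, match="mu"):
            SimConfig(season_mu={"summer": 0.9})
        with pytest.raises(ValueError, match="mu"):
            SimConfig(season_mu={"summer": 3.6})

    def test_bad_miss_prob_and_cutoffs(self):
        with pytest.raises(ValueError):
            SimConfig(miss_prob=1.0)
        with pytest.raises(ValueError):
            SimConfig(xmin_m=500.0, xmax_m=100.0)

    def test_fix_hours_must_increase(self):
        with pytest.raises(ValueError, match="fix_hours"):
            SimConfig(fix_hours=(dt.time(7, 30), dt.time(5, 30)))

    def test_missing_season_errors_with_month_name(self):
        cfg = SimConfig(start_date=dt.date(2015, 7, 1),
                        end_date=dt.date(2015, 7, 5),
                        season_mu={"summer": 2.44})
        with pytest.raises(ValueError, match="July"):
            simulate_levy_trajectory(cfg)


class TestTrajectorySimulation:
    def test_schedule_arithmetic(self):
        cfg = SimConfig(seed=1, start_date=dt.date(2015, 5, 1),
                        end_date=dt.date(2015, 5, 10), miss_prob=0.0)
        traj = simulate_levy_trajectory(cfg)
        assert len(traj) == 70  # 10 days x 7 scheduled fixes

    def test_missingness_reduces_fixes(self):
        cfg = SimConfig(seed=1, start_date=dt.date(2015, 5, 1),
                        end_date=dt.date(2015, 8, 31), miss_prob=0.3)
        traj = simulate_levy_trajectory(cfg)
        n_sched = 123 * 7
        assert len(traj) < n_sched
        # binomial(861, 0.7) stays within 5 sigma of its mean
        assert abs(len(traj) - 0.7 * n_sched) < 5 * np.sqrt(
            n_sched * 0.3 * 0.7)

    def test_cluster_phase_fixes_stay_in_disk(self):
        phase = ClusterPhase(dt.date(2015, 5, 3), 5, (2000.0, -1000.0))
        cfg = SimConfig(seed=2, start_date=dt.date(2015, 5, 1),
                        end_date=dt.date(2015, 5, 12),
                        cluster_phases=(phase,), xmin_m=50.0, xmax_m=40000.0)
        traj = simulate_levy_trajectory(cfg)
        xy = project(traj)
        centre = np.array(lonlat_to_utm43n(*cfg.origin_lonlat)) + \
            np.array(phase.center_offset_m)
        local_dates = traj.local_timestamps().dt.date
        in_phase = local_dates.map(phase.covers).to_numpy()
        assert in_phase.sum() == 5 * 7
        d = np.hypot(xy[in_phase, 0] - centre[0], xy[in_phase, 1] - centre[1])
        assert (d <= 50.0 + 0.01).all()

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=9, start_date=dt.date(2015, 5, 1),
                        end_date=dt.date(2015, 6, 1), miss_prob=0.1)
        a = simulate_levy_trajectory(cfg)
        b = simulate_levy_trajectory(cfg)
        assert a.fixes.equals(b.fixes)

    def test_exponent_recovered_from_simulated_steps(self):
        # all seasons share mu=2.5 so the whole walk is one regime
        cfg = SimConfig(seed=13, start_date=dt.date(2013, 1, 1),
                        end_date=dt.date(2016, 12, 1),
                        season_mu={s: 2.5 for s in
                                   ("summer", "monsoon", "post_monsoon",
                                    "winter")},
                        xmin_m=100.0)
        traj = simulate_levy_trajectory(cfg)
        steps = step_series(traj)
        assert len(steps) >= 10000
        fit = fit_power_law(steps.steps["length_m"].to_numpy(), xmin=100.0)
        assert fit.mu == pytest.approx(2.5, abs=0.05)

    def test_turning_angles_uniform(self):
        cfg = SimConfig(seed=17, start_date=dt.date(2014, 1, 1),
                        end_date=dt.date(2016, 1, 1))
        steps = step_series(simulate_levy_trajectory(cfg))
        counts, _, rbar = turning_histogram(steps, n_bins=36)
        assert counts.sum() >= 5000
        p = stats.chisquare(counts).pvalue
        assert p > 0.01
        assert rbar < 0.05


class TestStepSampler:
    @pytest.mark.parametrize("mu", [1.74, 2.10, 2.44, 2.89])
    def test_ccdf_log_log_slope(self, mu):
        rng = np.random.default_rng(42)
        x = np.sort(sample_step_lengths(20000, mu, 150.0, xmax=None,
                                        rng=rng))
        # least squares on the binned log CCDF vs log length
        edges = np.geomspace(150.0, np.quantile(x, 0.995), 21)
        xs, ys = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if ((x >= lo) & (x < hi)).sum() >= 5:
                xs.append(np.log(np.sqrt(lo * hi)))
                ys.append(np.log((x >= lo).mean()))
        slope = np.polyfit(xs, ys, 1)[0]
        assert abs(slope + mu - 1.0) < 0.1

    @pytest.mark.parametrize("mu", [1.74, 2.10, 2.44, 2.89])
    def test_parameter_recovery_at_study_sample_size(self, mu):
        # n = 3345 fixes' worth of steps, averaged over 20 seeds
        mus = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = sample_step_lengths(3345, mu, 150.0, 40000.0, rng)
            mus.append(fit_power_law(x, xmin=150.0).mu)
        assert np.mean(mus) == pytest.approx(mu, abs=0.1)

    def test_truncation_respected(self):
        rng = np.random.default_rng(0)
        x = sample_step_lengths(5000, 2.0, 100.0, 40000.0, rng)
        assert x.min() >= 100.0 and x.max() <= 40000.0

    def test_inverse_cdf_matches_closed_form_cdf(self):
        # empirical CDF of draws vs analytic truncated-Pareto CDF
        rng = np.random.default_rng(3)
        xmin, xmax, mu = 100.0, 10000.0, 2.2
        x = sample_step_lengths(20000, mu, xmin, xmax, rng)
        alpha = mu - 1.0
        cdf = lambda v: ((1 - (v / xmin) ** -alpha)
                         / (1 - (xmax / xmin) ** -alpha))
        D = stats.kstest(x, cdf).statistic
        assert D < 0.015  # ~ 1.63/sqrt(n) at alpha=0.01


class TestLandscape:
    EXTENT = (490000.0, 1960000.0, 510000.0, 1980000.0)

    def test_single_class_request(self):
        land = simulate_landscape(1, self.EXTENT, 500.0,
                                  class_probs={"open": 1.0})
        assert (land.landcover.values
                == land.classes.index("open")).all()

    def test_constant_ndvi(self):
        land = simulate_landscape(1, self.EXTENT, 500.0, constant_ndvi=0.31)
        for _, grid in land.ndvi_layers:
            assert (grid.values == 0.31).all()

    def test_ndvi_within_unit_interval(self):
        land = simulate_landscape(2, self.EXTENT, 500.0)
        for _, grid in land.ndvi_layers:
            assert grid.values.min() >= 0.0 and grid.values.max() <= 1.0

    def test_same_seed_identical(self):
        a = simulate_landscape(5, self.EXTENT, 500.0)
        b = simulate_landscape(5, self.EXTENT, 500.0)
        assert (a.landcover.values == b.landcover.values).all()
        for (da, ga), (db, gb) in zip(a.ndvi_layers, b.ndvi_layers):
            assert da == db and (ga.values == gb.values).all()
        assert all(la.equals(lb)
                   for la, lb in zip(a.powerlines, b.powerlines))
        assert all(ra.equals(rb) for ra, rb in zip(a.roads, b.roads))

    def test_lines_have_vertices_and_exist(self):
        land = simulate_landscape(7, self.EXTENT, 500.0)
        assert len(land.powerlines) >= 1 and len(land.roads) >= 1
        for line in land.powerlines + land.roads:
            assert len(line.coords) >= 2

    def test_extent_smaller_than_cell_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            simulate_landscape(1, (0.0, 0.0, 100.0, 100.0), 500.0)
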