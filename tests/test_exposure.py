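"""Exposure integration, estimator comparison, health categories, zone summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mobexpo.exposure import (
    CATEGORY_NAMES,
    ExposureSeries,
    away_exposure_relation,
    categorize,
    exposure_series,
    high_exposure_zone_summary,
    infer_home,
    ks_compare,
    locate_cell,
    paired_differences,
    recorded_hourly,
    static_hourly,
    three_way_estimates,
)
from mobexpo.pollution import Grid1km, PollutionSurface
from mobexpo.trajectory_io import HourlyTrajectory

from .conftest import make_traj


def flat_surface(grid, value, days=1):
    surf = PollutionSurface(grid=grid)
    for d in range(1, days + 1):
        for h in range(24):
            surf.data[(d, h)] = np.full(grid.n_cells, float(value))
    return surf


def hourly_at(grid_pos, days=1, user_id="u1"):
    x, y = grid_pos
    return HourlyTrajectory(user_id=user_id, points=[
        (d, h, x, y, "reconstructed") for d in range(1, days + 1) for h in range(24)])


@pytest.fixture()
def grid():
    return Grid1km(0, 0, 4, 4)


class TestCategories:
    @pytest.mark.parametrize("ap,expected", [
        (0.0, "Excellent"), (34.9, "Excellent"),
        (35.0, "Good"), (69.9, "Good"),
        (70.0, "LightlyPolluted"), (115.0, "ModeratelyPolluted"),
        (150.0, "SeverelyPolluted"), (1e6, "SeverelyPolluted"),
    ])
    def test_boundaries_left_closed(self, ap, expected):
        assert categorize(ap) == expected

    @given(st.floats(0, 500, allow_nan=False))
    def test_partition_every_value_once(self, ap):
        assert categorize(ap) in CATEGORY_NAMES

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize(-1.0)


class TestLocateCell:
    def test_conventions(self, grid):
        assert locate_cell(0.0, 0.0, grid) == (0, False)
        assert locate_cell(1000.0, 0.0, grid) == (1, False)
        cell, clamped = locate_cell(50000.0, 0.0, grid)
        assert clamped and cell == 3


class TestExposureSeries:
    def test_constant_surface_cumulative(self, grid):
        series = exposure_series(hourly_at((500, 500)), flat_surface(grid, 42.0))
        assert series.cumulative == pytest.approx(24 * 42.0)
        assert all(e[4] == "Good" for e in series.entries)

    def test_single_microenvironment_reduces_to_outdoor(self, grid):
        hourly = hourly_at((500, 500))
        me_tp = {(1, h): [(1.0, 1.0)] for h in range(24)}
        a = exposure_series(hourly, flat_surface(grid, 55.0), me_tp=me_tp)
        b = exposure_series(hourly, flat_surface(grid, 55.0))
        assert a.cumulative == pytest.approx(b.cumulative)

    def test_two_microenvironments_weighted(self, grid):
        hourly = HourlyTrajectory(user_id="u", points=[(1, 0, 500, 500, "observed")])
        me_tp = {(1, 0): [(0.6, 0.5), (1.0, 0.5)]}
        series = exposure_series(hourly, flat_surface(grid, 100.0), me_tp=me_tp)
        assert series.cumulative == pytest.approx(80.0)

    def test_tp_must_sum_to_one(self, grid):
        hourly = HourlyTrajectory(user_id="u", points=[(1, 0, 500, 500, "observed")])
        with pytest.raises(ValueError, match="sum"):
            exposure_series(hourly, flat_surface(grid, 10.0),
                            me_tp={(1, 0): [(1.0, 0.7)]})

    def test_additive_over_days(self, grid, rng):
        surf = PollutionSurface(grid=grid)
        for d in (1, 2):
            for h in range(24):
                surf.data[(d, h)] = rng.uniform(10, 90, grid.n_cells)
        both = exposure_series(hourly_at((1500, 1500), days=2), surf)
        day1 = exposure_series(
            HourlyTrajectory("u1", [(1, h, 1500, 1500, "observed") for h in range(24)]),
            surf)
        day2 = exposure_series(
            HourlyTrajectory("u1", [(2, h, 1500, 1500, "observed") for h in range(24)]),
            surf)
        assert both.cumulative == pytest.approx(day1.cumulative + day2.cumulative)

    def test_missing_surface_hour_rejected(self, grid):
        surf = PollutionSurface(grid=grid)
        surf.data[(1, 0)] = np.zeros(grid.n_cells)
        with pytest.raises(KeyError):
            exposure_series(hourly_at((500, 500)), surf)


def ks_brute_force(a, b):
    pts = np.concatenate([a, b])
    return max(abs((a <= t).mean() - (b <= t).mean()) for t in pts)


class TestKsCompare:
    def test_identical_samples(self):
        stat, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0

    def test_worked_example(self):
        stat, _ = ks_compare([1, 2, 3], [1, 2, 3, 100])
        assert stat == pytest.approx(0.25)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_ecdf_sup(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(1, 50))
        b = rng.normal(0.3, 1.2, rng.integers(1, 50))
        stat, _ = ks_compare(a, b)
        assert stat == pytest.approx(ks_brute_force(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestPairedDifferences:
    def test_equal_estimates_zero_median(self):
        est = {("u1", 1): 5.0, ("u2", 1): 7.0}
        out = paired_differences(est, dict(est), {1: "workday"})
        assert out["workday"]["median"] == 0.0

    def test_quartiles_by_linear_interpolation(self):
        a = {(f"u{i}", 1): float(v) for i, v in enumerate([-2, -1, 0, 1, 2])}
        b = {k: 0.0 for k in a}
        out = paired_differences(a, b, {1: "workday"})["workday"]
        assert out["median"] == 0.0
        assert (out["q1"], out["q3"]) == (-1.0, 1.0)
        assert out["iqr"] == 2.0

    def test_day_type_grouping_partitions(self):
        est_a = {("u1", 1): 1.0, ("u1", 6): 2.0}
        est_b = {("u1", 1): 0.0, ("u1", 6): 0.0}
        out = paired_differences(est_a, est_b, {1: "workday", 6: "weekend"})
        assert out["workday"]["n"] == 1 and out["weekend"]["n"] == 1

    def test_mismatched_users_listed(self):
        with pytest.raises(ValueError, match="u2"):
            paired_differences({("u1", 1): 1.0}, {("u2", 1): 1.0}, {})


class TestInferHome:
    def test_night_majority_wins(self):
        pts = [(1, 23 * 3600 + i, 10.0, 10.0) for i in range(10)]
        pts += [(1, 2 * 3600 + i, 99.0, 99.0) for i in range(2)]
        home, flagged = infer_home(make_traj(pts))
        assert home == (10.0, 10.0) and not flagged

    def test_2159_excluded_from_night(self):
        pts = [(1, 21 * 3600 + 59 * 60, 1.0, 1.0)] * 3 + [(1, 23 * 3600, 2.0, 2.0)]
        home, _ = infer_home(make_traj([(d, t + i, x, y)
                                        for i, (d, t, x, y) in enumerate(pts)]))
        assert home == (2.0, 2.0)

    def test_tie_break_deterministic(self):
        pts = [(1, 23 * 3600 + i * 60, 1.0, 1.0) for i in range(5)]
        pts += [(1, 1 * 3600 + i * 60, 2.0, 2.0) for i in range(5)]
        h1, _ = infer_home(make_traj(pts))
        h2, _ = infer_home(make_traj(pts))
        assert h1 == h2 == (2.0, 2.0)  # later night rank wins the tie

    def test_no_night_records_falls_back_to_modal(self):
        pts = [(1, 12 * 3600 + i * 60, 3.0, 3.0) for i in range(4)]
        pts += [(1, 13 * 3600, 4.0, 4.0)]
        home, flagged = infer_home(make_traj(pts))
        assert home == (3.0, 3.0) and flagged


class TestThreeWay:
    def test_stationary_user_all_equal(self, grid, rng):
        surf = PollutionSurface(grid=grid)
        for h in range(24):
            surf.data[(1, h)] = rng.uniform(20, 80, grid.n_cells)
        pts = [(1, h * 3600, 1500.0, 1500.0) for h in range(0, 24, 2)]
        traj = make_traj(pts)
        hourly = hourly_at((1500.0, 1500.0))
        est = three_way_estimates(traj, hourly, surf, home=(1500.0, 1500.0), days=1)
        assert est["tr"].cumulative == pytest.approx(est["rec"].cumulative)
        assert est["rec"].cumulative == pytest.approx(est["sl"].cumulative)

    def test_commuter_static_underestimates(self, grid):
        # high concentration at work cell, low at home cell
        surf = PollutionSurface(grid=grid)
        for h in range(24):
            field = np.full(grid.n_cells, 20.0)
            field[grid.cell_id(3, 3)] = 150.0
            surf.data[(1, h)] = field
        work, home = (3500.0, 3500.0), (500.0, 500.0)
        true_pts = [(1, h, *(work if 9 <= h <= 17 else home), "observed")
                    for h in range(24)]
        hourly = HourlyTrajectory("u1", true_pts)
        traj = make_traj([(1, h * 3600, *(work if 9 <= h <= 17 else home))
                          for h in range(24)])
        est = three_way_estimates(traj, hourly, surf, home=home, days=1)
        assert est["sl"].cumulative < est["tr"].cumulative

    def test_recorded_hourly_carries_forward(self, grid):
        traj = make_traj([(1, 6 * 3600, 100.0, 0.0), (1, 12 * 3600, 900.0, 0.0)])
        rec = recorded_hourly(traj, days=1)
        xs = [p[2] for p in rec.points]
        assert xs[:7] == [100.0] * 7  # leading hours back-filled
        assert xs[7:12] == [100.0] * 5
        assert xs[12:] == [900.0] * 12

    def test_static_hourly_fixed(self):
        sh = static_hourly("u", (5.0, 6.0), days=2)
        assert len(sh.points) == 48
        assert all(p[2:4] == (5.0, 6.0) for p in sh.points)


def make_series(user_id, cumulative, entries):
    return ExposureSeries(user_id=user_id, entries=entries, cumulative=cumulative)


class TestZoneSummary:
    def _series(self, grid, user_id, total, home_cell=(0, 0), away_hours=0, ap=50.0):
        entries = []
        home_id = grid.cell_id(*home_cell)
        for h in range(24):
            cell = home_id + 1 if h < away_hours else home_id
            entries.append((1, h, cell, ap, categorize(ap)))
        return make_series(user_id, total, entries)

    def test_top_fraction_selected(self, grid):
        series = {f"u{i}": self._series(grid, f"u{i}", float(i)) for i in range(10)}
        homes = {u: (500.0, 500.0) for u in series}
        out = high_exposure_zone_summary(series, homes, grid, top_frac=0.2)
        assert sum(z.n_high_exposure for z in out) == 2

    def test_category_percentages_sum_100(self, grid, rng):
        series = {}
        homes = {}
        for i in range(6):
            entries = [(1, h, 0, float(rng.uniform(0, 200)),
                        categorize(float(min(rng.uniform(0, 200), 1e9))))
                       for h in range(24)]
            entries = [(d, h, c, ap, categorize(ap)) for d, h, c, ap, _ in entries]
            series[f"u{i}"] = make_series(f"u{i}", float(i), entries)
            homes[f"u{i}"] = (500.0, 500.0)
        out = high_exposure_zone_summary(series, homes, grid, top_frac=1.0)
        for z in out:
            assert sum(z.category_pct.values()) == pytest.approx(100.0, abs=0.01)

    def test_all_identical_top_frac_one(self, grid):
        series = {f"u{i}": self._series(grid, f"u{i}", 10.0) for i in range(5)}
        homes = {u: (500.0, 500.0) for u in series}
        out = high_exposure_zone_summary(series, homes, grid, top_frac=1.0)
        assert sum(z.n_high_exposure for z in out) == 5

    def test_too_few_users(self, grid):
        with pytest.raises(ValueError):
            high_exposure_zone_summary({}, {}, grid)


class TestAwayRelation:
    def test_uniform_exposure_identity(self, grid):
        summaries = []
        for i, away in enumerate((4, 8, 16)):
            entries = [(1, h, (1 if h < away else 0), 50.0, "Good")
                       for h in range(24)]
            s = make_series(f"u{i}", 24 * 50.0, entries)
            out = high_exposure_zone_summary(
                {f"u{i}": s, **{f"v{j}": make_series(f"v{j}", 0.0, entries)
                                for j in range(4)}},
                {f"u{i}": (500.0, 500.0), **{f"v{j}": (500.0, 500.0)
                                             for j in range(4)}},
                grid, top_frac=0.2)
            summaries.extend(out)
        pairs, slope, r = away_exposure_relation(summaries)
        assert slope == pytest.approx(1.0)
        assert r == pytest.approx(1.0)
        for t, e in pairs:
            assert e == pytest.approx(t)

    def test_single_zone_rejected(self, grid):
        s = make_series("u", 1.0, [(1, 0, 0, 50.0, "Good")])
        with pytest.raises(ValueError):
            away_exposure_relation([high_exposure_zone_summary(
                {f"u{i}": s for i in range(5)},
                {f"u{i}": (500.0, 500.0) for i in range(5)}, grid)[0]])
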