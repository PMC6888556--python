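"""Training-set construction, boosted-tree reconstruction and baselines."""

import numpy as np
import pytest

from mobexpo.mobility import MobilityFeatures, compute_features
from mobexpo.reconstruction import (
    TrajectoryReconstructor,
    baseline_linear,
    baseline_nearest,
    build_training_set,
    evaluate_holdout,
    examples_to_arrays,
    holdout_split,
    reconstruct_hourly,
    resample_trajectory,
)

from .conftest import make_traj

FEATS = MobilityFeatures(user_id="u1", rog_m=1000.0, entropy_bits=1.0, n_locations=2)


def hourly_traj(n, user_id="u1", speed=100.0):
    """n records at exact hour marks, moving east at `speed` m/h."""
    return make_traj([(1 + (i // 24), (i % 24) * 3600, speed * i, 0.0)
                      for i in range(n)], user_id=user_id)


def brute_force_example_count(trajs, intervals):
    total = 0
    for traj in trajs:
        for iv in intervals:
            seq = resample_trajectory(traj, iv)
            total += max(0, len(seq) - 2)
    return total


class TestBuildTrainingSet:
    def test_five_records_native_interval(self):
        traj = hourly_traj(5)
        ex = build_training_set([traj], {"u1": FEATS}, resample_intervals=[3600])
        assert len(ex) == 3
        assert all(e.features[7] == FEATS.rog_m for e in ex)

    def test_two_records_no_examples(self):
        with pytest.raises(ValueError):
            build_training_set([hourly_traj(2)], {"u1": FEATS},
                               resample_intervals=[3600])

    def test_two_users_pooled_with_distinct_tails(self):
        t1, t2 = hourly_traj(3, "a"), hourly_traj(3, "b")
        feats = {"a": compute_features(t1),
                 "b": MobilityFeatures("b", 99.0, 0.5, 3)}
        ex = build_training_set([t1, t2], feats, resample_intervals=[3600])
        assert len(ex) == 2
        tails = {e.features[7:] for e in ex}
        assert len(tails) == 2

    def test_count_matches_brute_force_enumeration(self, rng):
        trajs = []
        for u in range(4):
            times = np.sort(rng.choice(86400 * 2, size=rng.integers(3, 40),
                                       replace=False))
            trajs.append(make_traj(
                [(1 + int(t) // 86400, int(t) % 86400,
                  float(rng.integers(0, 10000)), 0.0) for t in times],
                user_id=f"u{u}"))
        feats = {t.user_id: compute_features(t) for t in trajs}
        intervals = [3600, 7200, 10800]
        ex = build_training_set(trajs, feats, resample_intervals=intervals)
        assert len(ex) == brute_force_example_count(trajs, intervals)


class TestTrajectoryReconstructor:
    def test_constant_labels_predict_constant(self):
        X = np.random.default_rng(0).uniform(0, 100, (50, 9))
        X[:, 2], X[:, 3], X[:, 6] = 0, 1, 2  # keep t ordering sane
        Y = np.full((50, 2), 7.5)
        model = TrajectoryReconstructor(n_estimators=20).fit(X, Y)
        assert np.allclose(model.predict(X[:5]), 7.5)

    def test_seeded_fit_is_deterministic(self, rng):
        X = rng.uniform(0, 100, (80, 9))
        Y = rng.uniform(0, 100, (80, 2))
        probe = rng.uniform(0, 100, (10, 9))
        p1 = TrajectoryReconstructor(random_state=3, subsample=0.8).fit(X, Y).predict(probe)
        p2 = TrajectoryReconstructor(random_state=3, subsample=0.8).fit(X, Y).predict(probe)
        assert np.array_equal(p1, p2)

    def test_linear_motion_beats_centroid_predictor(self, rng):
        # examples from straight-line motion: x_mid determined by t_mid
        rows, labels = [], []
        for _ in range(300):
            t0 = rng.uniform(0, 1000)
            dt1, dt2 = rng.uniform(10, 50, 2)
            x0 = rng.uniform(0, 5000)
            v = rng.uniform(-5, 5)
            rows.append([x0, 0, t0, t0 + dt1, x0 + v * (dt1 + dt2), 0, t0 + dt1 + dt2,
                         1000.0, 1.0])
            labels.append([x0 + v * dt1, 0.0])
        X, Y = np.array(rows), np.array(labels)
        model = TrajectoryReconstructor(random_state=0).fit(X[:200], Y[:200])
        pred = model.predict(X[200:])
        mae_model = np.abs(pred - Y[200:]).mean()
        mae_centroid = np.abs(Y[:200].mean(axis=0) - Y[200:]).mean()
        assert mae_model < mae_centroid

    def test_too_few_examples_names_cluster(self):
        with pytest.raises(ValueError, match="cluster 5"):
            TrajectoryReconstructor(cluster_id=5).fit(np.zeros((3, 9)),
                                                      np.zeros((3, 2)))

    def test_persistence_round_trip(self, tmp_path, rng):
        X = rng.uniform(0, 100, (30, 9))
        Y = rng.uniform(0, 100, (30, 2))
        model = TrajectoryReconstructor(n_estimators=10).fit(X, Y)
        path = tmp_path / "model.joblib"
        model.save(path)
        again = TrajectoryReconstructor.load(path)
        assert np.array_equal(model.predict(X), again.predict(X))


class TestReconstructHourly:
    def test_all_hours_observed_pass_through(self):
        traj = hourly_traj(24)
        out = reconstruct_hourly(traj, model=None, feats=FEATS, days=1)
        assert all(p[4] == "observed" for p in out.points)
        assert [p[2] for p in out.points] == [100.0 * i for i in range(24)]

    def test_stationary_user_midpoint(self):
        pts = [(1, h * 3600, 500.0, 500.0) for h in range(24) if h != 12]
        traj = make_traj(pts)
        X, Y = examples_to_arrays(build_training_set(
            [make_traj([(1, h * 3600, 500.0, 500.0) for h in range(24)])],
            {"u1": FEATS}, resample_intervals=[3600]))
        model = TrajectoryReconstructor(n_estimators=20).fit(X, Y)
        out = reconstruct_hourly(traj, model, FEATS, days=1)
        day, hour, x, y, prov = out.points[12]
        assert prov == "reconstructed"
        assert (x, y) == pytest.approx((500.0, 500.0), abs=1.0)

    def test_edge_hours_nearest_filled(self):
        traj = make_traj([(1, 6 * 3600, 700.0, 0.0), (1, 7 * 3600, 800.0, 0.0)])
        out = reconstruct_hourly(traj, model=None, feats=FEATS, days=1)
        for h in range(6):
            assert out.points[h][2:4] == (700.0, 0.0)
        for h in range(8, 24):
            assert out.points[h][2:4] == (800.0, 0.0)

    def test_single_record_fallback(self):
        traj = make_traj([(1, 3600, 42.0, 24.0)])
        out = reconstruct_hourly(traj, model=None, feats=FEATS, days=1)
        assert len(out.points) == 24
        assert all(p[2:4] == (42.0, 24.0) for p in out.points)


class TestBaselines:
    def test_nearest_picks_temporally_closest(self):
        traj = make_traj([(1, 0, 0.0, 0.0), (1, 100, 100.0, 0.0)])
        pred = baseline_nearest(traj, [49, 51])
        assert pred[0].tolist() == [0.0, 0.0]
        assert pred[1].tolist() == [100.0, 0.0]

    def test_nearest_tie_takes_earlier(self):
        traj = make_traj([(1, 0, 0.0, 0.0), (1, 100, 100.0, 0.0)])
        assert baseline_nearest(traj, [50])[0].tolist() == [0.0, 0.0]

    def test_linear_midpoint(self):
        traj = make_traj([(1, 0, 0.0, 0.0), (1, 100, 100.0, 0.0)])
        assert baseline_linear(traj, [50])[0].tolist() == [50.0, 0.0]

    def test_linear_clamps_outside_span(self):
        traj = make_traj([(1, 100, 10.0, 0.0), (1, 200, 20.0, 0.0)])
        pred = baseline_linear(traj, [0, 300])
        assert pred[0].tolist() == [10.0, 0.0]
        assert pred[1].tolist() == [20.0, 0.0]

    def test_preconditions(self):
        with pytest.raises(ValueError):
            baseline_nearest(make_traj([]), [0])
        with pytest.raises(ValueError):
            baseline_linear(make_traj([(1, 0, 0, 0)]), [0])


class TestEvaluateHoldout:
    def _stationary_world(self):
        pts = [(1, h * 1800, 300.0, 300.0) for h in range(48)]
        evs = ["call_in" if h % 3 else "regular_update" for h in range(48)]
        traj = make_traj(pts)
        records = [r.__class__(user_id=r.user_id, day=r.day, t=r.t, x=r.x, y=r.y,
                               event_type=e) for r, e in zip(traj.records, evs)]
        return traj.__class__(user_id="u1", records=records)

    def test_stationary_user_zero_error(self):
        traj = self._stationary_world()
        feats = {"u1": compute_features(traj)}
        X = np.tile([300, 300, 0, 1, 300, 300, 2, 0, 0], (20, 1)).astype(float)
        X[:, 3] = np.arange(20) * 0.1 + 0.5
        model = TrajectoryReconstructor(n_estimators=10).fit(
            X, np.full((20, 2), 300.0))
        report = evaluate_holdout([traj], feats, {"u1": 0}, {0: model})
        for m in ("gbdt", "nearest", "linear"):
            assert report.per_method[m].mae == pytest.approx(0.0, abs=1e-9)

    def test_mae_stdev_match_stored_errors(self, small_world):
        from mobexpo.experiments import reconstruction_ranking

        rr = reconstruction_ranking(seed=7, world=small_world, n_clusters=2)
        assert set(rr.mae) == {"gbdt", "nearest", "linear"}
        assert all(v >= 0 for v in rr.mae.values())

    def test_event_type_split_partitions_records(self):
        traj = self._stationary_world()
        kept, held = holdout_split(traj, mode="event_type")
        assert len(kept) + len(held) == len(traj)
        assert all(r.event_type in ("call_in", "call_out", "sms")
                   for r in kept.records)

    def test_empty_heldout_rejected(self):
        traj = make_traj([(1, 0, 0, 0)])
        feats = {"u1": compute_features(traj)}
        with pytest.raises(ValueError):
            evaluate_holdout([traj], feats, {"u1": 0}, {})
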