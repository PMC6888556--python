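"""Trajectory reconstruction with gradient-boosted trees + interpolation baselines.

Sparse traces are densified to an hourly grid. Within each movement-pattern
cluster, training examples are formed from consecutive point triples of
resampled trajectories: the two outer points plus the middle point's time
(and the user's global mobility descriptors) are the features, the middle
point's location is the label. Two boosted-tree regressors — one per output
coordinate, CART weak learners — learn to place the midpoint. Pooling a whole
cluster's trajectories gives each model far more data than any single user
could provide, which is what lifts it over per-user interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import GradientBoostingRegressor

from .mobility import MobilityFeatures
from .trajectory_io import (
    CDR_EVENT_TYPES,
    HourlyTrajectory,
    Trajectory,
    TrajectoryRecord,
    hourly_grid_times,
    split_observed_hours,
)

FEATURE_NAMES = ("x_prev", "y_prev", "t_prev", "t_mid", "x_next", "y_next", "t_next",
                 "rog", "entropy")


@dataclass(frozen=True)
class TrainingExample:
    """One (context, midpoint) pair: features per FEATURE_NAMES, label (x, y)."""

    features: tuple[float, ...]
    label: tuple[float, float]

    def __post_init__(self) -> None:
        t_prev, t_mid, t_next = self.features[2], self.features[3], self.features[6]
        if not (t_prev < t_mid < t_next):
            raise ValueError("training example requires t_prev < t_mid < t_next")


def resample_trajectory(traj: Trajectory, interval_s: float) -> list[TrajectoryRecord]:
    """Thin a trajectory to records at least ``interval_s`` apart (greedy from the first)."""
    out: list[TrajectoryRecord] = []
    last_t = -np.inf
    for r in traj.records:
        if r.abs_t >= last_t + interval_s:
            out.append(r)
            last_t = r.abs_t
    return out


def build_training_set(
    trajectories: Iterable[Trajectory],
    features_by_user: dict[str, MobilityFeatures],
    resample_intervals: Sequence[float] = (3600.0, 7200.0, 10800.0),
) -> list[TrainingExample]:
    """Pool consecutive-triple examples over all users in a cluster.

    Each trajectory is subsampled at every stated interval; every interior
    point of a resampled sequence yields one example. Raises if no trajectory
    provides at least three records.
    """
    examples: list[TrainingExample] = []
    any_usable = False
    for traj in trajectories:
        if len(traj) >= 3:
            any_usable = True
        mf = features_by_user[traj.user_id]
        for interval in resample_intervals:
            seq = resample_trajectory(traj, interval)
            for i in range(1, len(seq) - 1):
                p, m, nx = seq[i - 1], seq[i], seq[i + 1]
                examples.append(TrainingExample(
                    features=(p.x, p.y, p.abs_t, m.abs_t, nx.x, nx.y, nx.abs_t,
                              mf.rog_m, mf.entropy_bits),
                    label=(m.x, m.y),
                ))
    if not any_usable:
        raise ValueError("no trajectory with >= 3 records; cannot build a training set")
    return examples


def examples_to_arrays(examples: Sequence[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([e.features for e in examples], dtype=float)
    Y = np.array([e.label for e in examples], dtype=float)
    return X, Y


class TrajectoryReconstructor(BaseEstimator, RegressorMixin):
    """Midpoint predictor: two gradient-boosted CART ensembles, one per coordinate.

    Parameters mirror the underlying boosted-tree regressors; ``random_state``
    makes fits bit-reproducible. ``min_train_examples`` guards against
    fitting a cluster model on too little data.

    Fitted attributes: ``model_x_``, ``model_y_``, ``n_train_``.
    """

    def __init__(self, n_estimators: int = 200, max_depth: int = 3,
                 learning_rate: float = 0.1, subsample: float = 1.0,
                 random_state: int = 0, min_train_examples: int = 10,
                 cluster_id: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.random_state = random_state
        self.min_train_examples = min_train_examples
        self.cluster_id = cluster_id

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must be (n, {len(FEATURE_NAMES)})")
        if len(X) < self.min_train_examples:
            raise ValueError(
                f"cluster {self.cluster_id}: {len(X)} training examples "
                f"< min_train_examples={self.min_train_examples}"
            )
        kwargs = dict(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, subsample=self.subsample,
            random_state=self.random_state,
        )
        self.model_x_ = GradientBoostingRegressor(**kwargs).fit(X, Y[:, 0])
        self.model_y_ = GradientBoostingRegressor(**kwargs).fit(X, Y[:, 1])
        self.n_train_ = len(X)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([self.model_x_.predict(X), self.model_y_.predict(X)])

    def save(self, path) -> None:
        import joblib

        joblib.dump({"format": 1, "params": self.get_params(),
                     "model_x": self.model_x_, "model_y": self.model_y_,
                     "n_train": self.n_train_}, path)

    @classmethod
    def load(cls, path) -> "TrajectoryReconstructor":
        import joblib

        blob = joblib.load(path)
        if blob.get("format") != 1:
            raise ValueError(f"unknown model file format {blob.get('format')!r}")
        est = cls(**blob["params"])
        est.model_x_ = blob["model_x"]
        est.model_y_ = blob["model_y"]
        est.n_train_ = blob["n_train"]
        return est


def _bracketing_records(
    records: Sequence[TrajectoryRecord], t: float
) -> tuple[TrajectoryRecord | None, TrajectoryRecord | None]:
    """Nearest records strictly before/at and after/at absolute time t."""
    prev = next_ = None
    for r in records:
        if r.abs_t <= t:
            prev = r
        elif next_ is None:
            next_ = r
            break
    return prev, next_


def predict_point(
    model: TrajectoryReconstructor,
    records: Sequence[TrajectoryRecord],
    t: float,
    feats: MobilityFeatures,
) -> tuple[float, float]:
    """Predict a location at absolute time t from the nearest observed context.

    Falls back to the nearest record's location when only one side of the
    bracket exists (trajectory ends) or when a record coincides with t.
    """
    prev, nxt = _bracketing_records(records, t)
    if prev is not None and prev.abs_t == t:
        return prev.x, prev.y
    if prev is None or nxt is None:
        r = prev if prev is not None else nxt
        return r.x, r.y
    X = np.array([[prev.x, prev.y, prev.abs_t, t, nxt.x, nxt.y, nxt.abs_t,
                   feats.rog_m, feats.entropy_bits]])
    xy = model.predict(X)[0]
    return float(xy[0]), float(xy[1])


def reconstruct_hourly(
    traj: Trajectory,
    model: TrajectoryReconstructor,
    feats: MobilityFeatures,
    snap_tol_s: float = 900.0,
    days: int | None = None,
) -> HourlyTrajectory:
    """Fill the full hourly grid: observed hours pass through, the rest are predicted.

    Hours before the first or after the last record are filled with the
    nearest observed location. Users with < 2 records get all hours at their
    single recorded location (degenerate fallback).
    """
    if days is None:
        days = max(traj.n_days, 1)
    if len(traj) < 2:
        if len(traj) == 0:
            raise ValueError(f"user {traj.user_id}: empty trajectory")
        r = traj.records[0]
        points = [(d, h, r.x, r.y, "reconstructed") for d, h in hourly_grid_times(days)]
        return HourlyTrajectory(user_id=traj.user_id, points=points)

    observed, missing = split_observed_hours(traj, snap_tol_s=snap_tol_s, days=days)
    obs_map = {(d, h): (x, y) for d, h, x, y in observed}
    points = []
    for day, hour in hourly_grid_times(days):
        if (day, hour) in obs_map:
            x, y = obs_map[(day, hour)]
            points.append((day, hour, x, y, "observed"))
        else:
            t = (day - 1) * 86400 + hour * 3600
            x, y = predict_point(model, traj.records, t, feats)
            points.append((day, hour, x, y, "reconstructed"))
    return HourlyTrajectory(user_id=traj.user_id, points=points)


def baseline_nearest(traj: Trajectory, times: Sequence[float]) -> np.ndarray:
    """Location of the temporally closest record per target time (tie -> earlier)."""
    if len(traj) == 0:
        raise ValueError("nearest interpolation needs >= 1 record")
    rec_t = np.array([r.abs_t for r in traj.records])
    pts = np.array([(r.x, r.y) for r in traj.records])
    out = np.empty((len(times), 2))
    for i, t in enumerate(times):
        off = np.abs(rec_t - t)
        out[i] = pts[int(np.argmin(off))]  # argmin takes the earliest on ties
    return out


def baseline_linear(traj: Trajectory, times: Sequence[float]) -> np.ndarray:
    """Affine interpolation between bracketing records, clamped outside the span."""
    if len(traj) < 2:
        raise ValueError("linear interpolation needs >= 2 records")
    rec_t = np.array([r.abs_t for r in traj.records])
    xs = np.array([r.x for r in traj.records])
    ys = np.array([r.y for r in traj.records])
    order = np.argsort(rec_t, kind="stable")
    rec_t, xs, ys = rec_t[order], xs[order], ys[order]
    times = np.asarray(times, dtype=float)
    return np.column_stack([np.interp(times, rec_t, xs), np.interp(times, rec_t, ys)])


@dataclass
class MethodErrors:
    mae: float
    stdev: float
    errors: np.ndarray  # per held-out point Euclidean errors, meters


@dataclass
class ReconstructionReport:
    per_method: dict[str, MethodErrors] = field(default_factory=dict)
    n_heldout: int = 0


def holdout_split(
    traj: Trajectory, mode: str = "event_type", held_fraction: float = 0.66,
    seed: int = 0,
) -> tuple[Trajectory, list[TrajectoryRecord]]:
    """Partition one user's records into kept and held-out sets.

    ``event_type`` mode keeps communication-driven records (call detail
    records) and holds out network-generated ones, mirroring an evaluation
    where the sparse CDR subset must recover the denser full trace. If a user
    has only one event class, a seeded Bernoulli(held_fraction) split is used
    instead (also the behaviour of mode="random").
    """
    recs = traj.records
    if mode == "event_type":
        kept = [r for r in recs if r.event_type in CDR_EVENT_TYPES]
        held = [r for r in recs if r.event_type not in CDR_EVENT_TYPES]
        if kept and held:
            return Trajectory(user_id=traj.user_id, records=kept), held
    rng = np.random.default_rng([seed, abs(hash(traj.user_id)) % (2**31)])
    mask = rng.random(len(recs)) < held_fraction
    if mask.all():
        mask[0] = False
    kept = [r for r, m in zip(recs, mask) if not m]
    held = [r for r, m in zip(recs, mask) if m]
    return Trajectory(user_id=traj.user_id, records=kept), held


def evaluate_holdout(
    trajectories: Sequence[Trajectory],
    features_by_user: dict[str, MobilityFeatures],
    cluster_of: dict[str, int],
    models: dict[int, TrajectoryReconstructor],
    holdout_mode: str = "event_type",
    held_fraction: float = 0.66,
    seed: int = 0,
    methods: Sequence[str] = ("gbdt", "nearest", "linear"),
) -> ReconstructionReport:
    """Held-out evaluation: per-method MAE and StDev of Euclidean errors.

    All methods are scored on the identical held-out set; per-point error
    lists are retained so the summary statistics are recomputable.
    """
    per_point: dict[str, list[float]] = {m: [] for m in methods}
    n_held = 0
    for traj in trajectories:
        kept, held = holdout_split(traj, mode=holdout_mode,
                                   held_fraction=held_fraction, seed=seed)
        if not held or len(kept) < 2:
            continue
        n_held += len(held)
        times = [r.abs_t for r in held]
        truth = np.array([(r.x, r.y) for r in held])
        for m in methods:
            if m == "nearest":
                pred = baseline_nearest(kept, times)
            elif m == "linear":
                pred = baseline_linear(kept, times)
            elif m == "gbdt":
                model = models[cluster_of[traj.user_id]]
                feats = features_by_user[traj.user_id]
                pred = np.array([predict_point(model, kept.records, t, feats) for t in times])
            else:
                raise ValueError(f"unknown method {m!r}")
            per_point[m].extend(np.hypot(*(pred - truth).T).tolist())
    if n_held == 0:
        raise ValueError("empty held-out set")
    report = ReconstructionReport(n_heldout=n_held)
    for m in methods:
        errs = np.array(per_point[m])
        report.per_method[m] = MethodErrors(
            mae=float(errs.mean()), stdev=float(errs.std()), errors=errs
        )
    return report


def fit_cluster_models(
    trajectories: Sequence[Trajectory],
    features_by_user: dict[str, MobilityFeatures],
    cluster_of: dict[str, int],
    resample_intervals: Sequence[float] = (3600.0, 7200.0, 10800.0),
    seed: int = 0,
    **gbdt_params,
) -> dict[int, TrajectoryReconstructor]:
    """One pooled reconstruction model per cluster.

    Clusters too sparse to train (fewer than ``min_train_examples`` triples)
    fall back to the globally pooled model.
    """
    by_cluster: dict[int, list[Trajectory]] = {}
    for traj in trajectories:
        by_cluster.setdefault(cluster_of[traj.user_id], []).append(traj)
    global_examples = build_training_set(trajectories, features_by_user, resample_intervals)
    Xg, Yg = examples_to_arrays(global_examples)
    global_model = TrajectoryReconstructor(random_state=seed, **gbdt_params).fit(Xg, Yg)
    models: dict[int, TrajectoryReconstructor] = {}
    for cid, trajs in by_cluster.items():
        try:
            ex = build_training_set(trajs, features_by_user, resample_intervals)
            X, Y = examples_to_arrays(ex)
            models[cid] = TrajectoryReconstructor(
                random_state=seed, cluster_id=cid, **gbdt_params
            ).fit(X, Y)
        except ValueError:
            models[cid] = global_model
    return models
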