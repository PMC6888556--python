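"""Individual exposure integration, estimator comparison, and health summaries.

Exposure of individual j over a study window is the sum over hours of the
PM2.5 concentration at the occupied 1-km cell,

    Exp'_j = sum_t AP_{i(t), t}        (outdoor-only simplification)

optionally refined by microenvironment ratios ME and time fractions TP,

    Exp_j = sum_t sum_n AP_{i,t} * ME_{i,n,t} * TP_{i,n,t}.

Three estimators are compared: TR (reconstructed hourly trajectory), REC (raw
records carried forward between observations) and SL (static home location).
Hourly concentrations map to five health categories; high-exposure residents
are aggregated by home zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .pollution import Grid1km, PollutionSurface
from .reconstruction import baseline_nearest
from .trajectory_io import HourlyTrajectory, Trajectory, hourly_grid_times, split_observed_hours

#: Ambient-air-quality categories, ug/m3; left-closed right-open bins
#: partitioning [0, inf).
HEALTH_CATEGORIES = (
    ("Excellent", 0.0, 35.0),
    ("Good", 35.0, 70.0),
    ("LightlyPolluted", 70.0, 115.0),
    ("ModeratelyPolluted", 115.0, 150.0),
    ("SeverelyPolluted", 150.0, math.inf),
)
CATEGORY_NAMES = tuple(name for name, _, _ in HEALTH_CATEGORIES)


def categorize(ap: float) -> str:
    """Health category of a concentration; boundaries go to the upper bin."""
    if ap < 0:
        raise ValueError(f"negative concentration {ap}")
    for name, lo, hi in HEALTH_CATEGORIES:
        if lo <= ap < hi:
            return name
    raise AssertionError("unreachable: bins cover [0, inf)")


def locate_cell(x: float, y: float, grid: Grid1km) -> tuple[int, bool]:
    """Flat cell id of a point (half-open cells; outside points clamp, flagged)."""
    row, col, clamped = grid.locate(x, y)
    return grid.cell_id(row, col), clamped


@dataclass
class ExposureSeries:
    """Per-hour occupied cell, concentration and category, plus the cumulative total."""

    user_id: str
    entries: list[tuple[int, int, int, float, str]]  # (day, hour, cell, ap, category)
    cumulative: float
    n_outside_grid: int = 0


def exposure_series(
    hourly: HourlyTrajectory,
    surface: PollutionSurface,
    me_tp: dict[tuple[int, int], Sequence[tuple[float, float]]] | None = None,
) -> ExposureSeries:
    """Integrate a complete hourly trajectory against the pollution surface.

    ``me_tp`` optionally maps (day, hour) to [(ME, TP), ...] microenvironment
    pairs whose TP must sum to 1 per hour; omitted, each hour contributes the
    plain outdoor concentration.
    """
    entries = []
    cumulative = 0.0
    n_outside = 0
    for day, hour, x, y, _ in hourly.points:
        ap, clamped = surface.value_at(day, hour, x, y)
        n_outside += clamped
        cell, _ = locate_cell(x, y, surface.grid)
        if me_tp is not None and (day, hour) in me_tp:
            pairs = me_tp[(day, hour)]
            tp_sum = sum(tp for _, tp in pairs)
            if abs(tp_sum - 1.0) > 1e-9:
                raise ValueError(
                    f"TP fractions for day {day} hour {hour} sum to {tp_sum}, expected 1"
                )
            contrib = sum(ap * me * tp for me, tp in pairs)
        else:
            contrib = ap
        cumulative += contrib
        entries.append((day, hour, cell, ap, categorize(ap)))
    return ExposureSeries(user_id=hourly.user_id, entries=entries,
                          cumulative=cumulative, n_outside_grid=n_outside)


def recorded_hourly(traj: Trajectory, days: int, snap_tol_s: float = 900.0) -> HourlyTrajectory:
    """Hourly positions from raw records only: last observation carried forward.

    Hours before the first observation are back-filled with it. Observed hours
    keep provenance "observed"; carried hours are "reconstructed".
    """
    observed, _ = split_observed_hours(traj, snap_tol_s=snap_tol_s, days=days)
    if not observed and traj.records:
        # no record close to any hour mark: treat each hour via nearest record
        pts = baseline_nearest(traj, [(d - 1) * 86400 + h * 3600
                                      for d, h in hourly_grid_times(days)])
        points = [(d, h, float(p[0]), float(p[1]), "reconstructed")
                  for (d, h), p in zip(hourly_grid_times(days), pts)]
        return HourlyTrajectory(user_id=traj.user_id, points=points)
    obs_map = {(d, h): (x, y) for d, h, x, y in observed}
    points = []
    last: tuple[float, float] | None = None
    for day, hour in hourly_grid_times(days):
        if (day, hour) in obs_map:
            last = obs_map[(day, hour)]
            points.append((day, hour, last[0], last[1], "observed"))
        else:
            points.append((day, hour, np.nan, np.nan, "reconstructed"))
    # forward-fill, then back-fill the leading gap
    first_loc = observed[0][2], observed[0][3]
    filled = []
    last = first_loc
    for day, hour, x, y, prov in points:
        if math.isnan(x):
            x, y = last
        else:
            last = (x, y)
        filled.append((day, hour, x, y, prov))
    return HourlyTrajectory(user_id=traj.user_id, points=filled)


def static_hourly(user_id: str, home: tuple[float, float], days: int) -> HourlyTrajectory:
    """Hourly trajectory pinned at the home location for every hour."""
    return HourlyTrajectory(
        user_id=user_id,
        points=[(d, h, home[0], home[1], "reconstructed") for d, h in hourly_grid_times(days)],
    )


def three_way_estimates(
    traj: Trajectory,
    reconstructed: HourlyTrajectory,
    surface: PollutionSurface,
    home: tuple[float, float],
    days: int,
    snap_tol_s: float = 900.0,
) -> dict[str, ExposureSeries]:
    """TR / REC / SL exposure estimates of one user, all via the same integrator."""
    return {
        "tr": exposure_series(reconstructed, surface),
        "rec": exposure_series(recorded_hourly(traj, days, snap_tol_s), surface),
        "sl": exposure_series(static_hourly(traj.user_id, home, days), surface),
    }


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic sup|ECDF_a - ECDF_b| and asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def paired_differences(
    est_a: dict[tuple[str, int], float],
    est_b: dict[tuple[str, int], float],
    day_types: dict[int, str],
) -> dict[str, dict[str, float]]:
    """Per-(user, day) differences a-b grouped by day type, summarized for box plots.

    Quartiles use linear interpolation. Raises if the two estimates cover
    different (user, day) sets.
    """
    if set(est_a) != set(est_b):
        missing = sorted(set(est_a) ^ set(est_b))
        raise ValueError(f"estimate key sets differ; symmetric difference: {missing[:10]}")
    groups: dict[str, list[float]] = {}
    for key in est_a:
        _, day = key
        groups.setdefault(day_types.get(day, "workday"), []).append(est_a[key] - est_b[key])
    out = {}
    for day_type, diffs in groups.items():
        arr = np.asarray(diffs, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[day_type] = {"median": float(med), "q1": float(q1), "q3": float(q3),
                         "iqr": float(q3 - q1), "n": int(len(arr))}
    return out


def infer_home(
    traj: Trajectory, night_start: int = 22, night_end: int = 6
) -> tuple[tuple[float, float], bool]:
    """Most frequently visited location during nighttime [22:00, 06:00).

    Tie-break: the tied location holding the latest record within the night
    window (measured from the evening start), then lexicographic. Without any
    nighttime record, falls back to the overall modal location (flag True).
    """
    start_s, end_s = night_start * 3600, night_end * 3600

    def night_rank(t: float) -> float | None:
        if t >= start_s:
            return t - start_s
        if t < end_s:
            return t + (86400 - start_s)
        return None

    counts: dict[tuple[float, float], int] = {}
    latest: dict[tuple[float, float], float] = {}
    for r in traj.records:
        rank = night_rank(r.t)
        if rank is None:
            continue
        loc = (r.x, r.y)
        counts[loc] = counts.get(loc, 0) + 1
        latest[loc] = max(latest.get(loc, -1.0), rank)
    if counts:
        best = max(counts, key=lambda loc: (counts[loc], latest[loc],
                                            tuple(-c for c in loc)))
        return best, False
    if not traj.records:
        raise ValueError(f"user {traj.user_id}: empty trajectory")
    overall: dict[tuple[float, float], int] = {}
    for r in traj.records:
        overall[(r.x, r.y)] = overall.get((r.x, r.y), 0) + 1
    best = max(overall, key=lambda loc: (overall[loc], tuple(-c for c in loc)))
    return best, True


@dataclass
class ZoneExposureSummary:
    zone_id: str
    n_high_exposure: int
    category_pct: dict[str, float] = field(default_factory=dict)
    time_away_pct: float = 0.0
    exposure_away_pct: float = 0.0


def high_exposure_zone_summary(
    series_by_user: dict[str, ExposureSeries],
    homes: dict[str, tuple[float, float]],
    grid: Grid1km,
    zones=None,
    top_frac: float = 0.2,
) -> list[ZoneExposureSummary]:
    """Aggregate the top-``top_frac`` users by cumulative exposure over home zones.

    Per zone: resident count, time share per health category, share of hours
    spent away from the home cell, and the share of exposure accrued in those
    away hours. Zones default to 1-km grid cells when no polygons are given.
    """
    n = len(series_by_user)
    if n < 5:
        raise ValueError(f"need >= 5 users, got {n}")
    k = math.ceil(top_frac * n)
    ranked = sorted(series_by_user, key=lambda u: -series_by_user[u].cumulative)
    selected = ranked[:k]

    def home_zone(user: str) -> str:
        hx, hy = homes[user]
        if zones is not None:
            from shapely.geometry import Point

            for z in sorted(zones, key=lambda z: z.zone_id):
                if z.geometry.covers(Point(hx, hy)):
                    return z.zone_id
        row, col, _ = grid.locate(hx, hy)
        return f"cell_{row}_{col}"

    by_zone: dict[str, list[str]] = {}
    for user in selected:
        by_zone.setdefault(home_zone(user), []).append(user)

    summaries = []
    for zone_id, users in sorted(by_zone.items()):
        cat_hours = {name: 0 for name in CATEGORY_NAMES}
        away_hours = total_hours = 0
        away_ap = total_ap = 0.0
        for user in users:
            series = series_by_user[user]
            home_cell, _ = locate_cell(*homes[user], grid)
            for _, _, cell, ap, cat in series.entries:
                cat_hours[cat] += 1
                total_hours += 1
                total_ap += ap
                if cell != home_cell:
                    away_hours += 1
                    away_ap += ap
        summaries.append(ZoneExposureSummary(
            zone_id=zone_id,
            n_high_exposure=len(users),
            category_pct={name: 100.0 * c / total_hours for name, c in cat_hours.items()},
            time_away_pct=100.0 * away_hours / total_hours,
            exposure_away_pct=100.0 * away_ap / total_ap if total_ap > 0 else 0.0,
        ))
    return summaries


def away_exposure_relation(
    summaries: Sequence[ZoneExposureSummary],
) -> tuple[list[tuple[float, float]], float, float]:
    """Per-zone (time-away %, exposure-away %) pairs with OLS slope and Pearson r."""
    if len(summaries) < 2:
        raise ValueError("need >= 2 zones for the away-time/exposure relation")
    pairs = [(s.time_away_pct, s.exposure_away_pct) for s in summaries]
    xs, ys = zip(*pairs)
    if np.ptp(xs) == 0:
        raise ValueError("degenerate zones: identical time-away percentages")
    res = stats.linregress(xs, ys)
    return pairs, float(res.slope), float(res.rvalue)
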