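"""Mobility-trace data model, CSV readers/writers, preprocessing and hourly targets.

Traces are sparse, irregular location records of the kind produced by mobile
networks: a record exists only when an event happens (a call, a text, a
cellular handover, a periodic network update), so the time between records is
bursty and heavy-tailed. All internal computation is in planar meters;
longitude/latitude inputs are projected once at read time.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

EVENT_TYPES = (
    "call_in",
    "call_out",
    "sms",
    "regular_update",
    "periodic_update",
    "handover",
)

#: Event types generated only when the user actively communicates (call detail
#: records); the complement is network-generated ("actively generated" by the
#: network without user action).
CDR_EVENT_TYPES = frozenset({"call_in", "call_out", "sms"})
ACTIVE_EVENT_TYPES = frozenset(EVENT_TYPES) - CDR_EVENT_TYPES

SECONDS_PER_DAY = 86400
EARTH_RADIUS_M = 6371008.8


@dataclass(frozen=True)
class TrajectoryRecord:
    """One timestamped location observation of one user."""

    user_id: str
    day: int  # 1-based day index
    t: float  # seconds since day start, in [0, 86400)
    x: float  # planar easting, meters
    y: float  # planar northing, meters
    event_type: str

    def __post_init__(self) -> None:
        if not (0 <= self.t < SECONDS_PER_DAY):
            raise ValueError(f"t={self.t} outside [0, {SECONDS_PER_DAY})")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"unknown event_type {self.event_type!r}; accepted: {', '.join(EVENT_TYPES)}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("x and y must be finite")

    @property
    def abs_t(self) -> float:
        """Seconds since the start of day 1."""
        return (self.day - 1) * SECONDS_PER_DAY + self.t


@dataclass
class Trajectory:
    """Time-ordered records of a single user (stable sort on input order)."""

    user_id: str
    records: list[TrajectoryRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.day, r.t))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_days(self) -> int:
        return max((r.day for r in self.records), default=0)


@dataclass
class HourlyTrajectory:
    """Complete hourly positions of one user: 24 x D points, observed or reconstructed."""

    user_id: str
    points: list[tuple[int, int, float, float, str]]  # (day, hour, x, y, provenance)

    def __post_init__(self) -> None:
        for _, _, _, _, prov in self.points:
            if prov not in ("observed", "reconstructed"):
                raise ValueError(f"bad provenance {prov!r}")

    def positions(self) -> list[tuple[float, float]]:
        return [(x, y) for _, _, x, y, _ in self.points]


def _parse_time_to_seconds(text: str) -> float:
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"cannot parse time {text!r} (expected HH:MM[:SS])")
    h, m = int(parts[0]), int(parts[1])
    s = float(parts[2]) if len(parts) == 3 else 0.0
    return h * 3600 + m * 60 + s


def _format_seconds(t: float) -> str:
    ti = int(round(t))
    return f"{ti // 3600:02d}:{(ti % 3600) // 60:02d}:{ti % 60:02d}"


def project_lonlat(
    lon: Sequence[float], lat: Sequence[float], lon0: float | None = None, lat0: float | None = None
) -> tuple[list[float], list[float], tuple[float, float]]:
    """Equirectangular projection to planar meters about (lon0, lat0).

    Default center is the data centroid. Adequate for city-scale extents where
    metric distance thresholds (hundreds of meters) must be honoured.
    """
    if lon0 is None:
        lon0 = sum(lon) / len(lon)
    if lat0 is None:
        lat0 = sum(lat) / len(lat)
    k = math.pi / 180.0 * EARTH_RADIUS_M
    coslat0 = math.cos(math.radians(lat0))
    xs = [(lo - lon0) * k * coslat0 for lo in lon]
    ys = [(la - lat0) * k for la in lat]
    return xs, ys, (lon0, lat0)


REQUIRED_COLUMNS = ["user_id", "day", "time", "x", "y", "event_type"]


def read_trajectories(path, crs_mode: str = "planar") -> list[Trajectory]:
    """Read a trace CSV (columns user_id,day,time,x,y,event_type) into per-user trajectories.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    crs_mode : {"planar", "lonlat"}
        "planar": x/y are already meters. "lonlat": x/y are degrees and are
        projected to meters (equirectangular about the data centroid).

    Returns
    -------
    list of Trajectory, one per distinct user_id, each time-sorted. Order of
    users follows first appearance in the file.
    """
    if crs_mode not in ("planar", "lonlat"):
        raise ValueError(f"crs_mode must be 'planar' or 'lonlat', got {crs_mode!r}")
    rows: list[tuple[str, int, float, float, float, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != REQUIRED_COLUMNS:
            raise ValueError(
                f"bad header {reader.fieldnames}; expected columns {REQUIRED_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                user = row["user_id"].strip()
                day = int(row["day"])
                t = _parse_time_to_seconds(row["time"])
                x = float(row["x"])
                y = float(row["y"])
                ev = row["event_type"].strip()
            except (TypeError, ValueError, AttributeError, KeyError) as exc:
                raise ValueError(f"malformed row at line {lineno}: {exc}") from exc
            if ev not in EVENT_TYPES:
                raise ValueError(
                    f"unknown event_type {ev!r} at line {lineno}; "
                    f"accepted values: {', '.join(EVENT_TYPES)}"
                )
            rows.append((user, day, t, x, y, ev))

    if crs_mode == "lonlat" and rows:
        xs, ys, _ = project_lonlat([r[3] for r in rows], [r[4] for r in rows])
        rows = [(u, d, t, x, y, e) for (u, d, t, _, _, e), x, y in zip(rows, xs, ys)]

    by_user: dict[str, list[TrajectoryRecord]] = {}
    for user, day, t, x, y, ev in rows:
        by_user.setdefault(user, []).append(
            TrajectoryRecord(user_id=user, day=day, t=t, x=x, y=y, event_type=ev)
        )
    return [Trajectory(user_id=u, records=recs) for u, recs in by_user.items()]


def write_trajectories(trajectories: Iterable[Trajectory], path) -> None:
    """Write trajectories back to the input CSV schema (planar coordinates)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for traj in trajectories:
            for r in traj.records:
                writer.writerow(
                    [r.user_id, r.day, _format_seconds(r.t), repr(r.x), repr(r.y), r.event_type]
                )


def suppress_oscillation(
    traj: Trajectory, window_s: float = 300.0, max_jump_m: float = 2000.0
) -> Trajectory:
    """Collapse A->B->A ping-pong patterns caused by cell-tower oscillation.

    Every maximal pattern where the trace jumps from location A to one other
    location B and back to A, with each transition within ``window_s`` seconds
    and |A-B| <= ``max_jump_m`` meters, is collapsed by deleting the middle B
    record(s). Applied to a fixpoint, so the operation is idempotent and the
    surviving records are a subsequence of the input.
    """
    if window_s < 0 or max_jump_m < 0:
        raise ValueError("window_s and max_jump_m must be non-negative")
    records = list(traj.records)
    changed = True
    while changed:
        changed = False
        out: list[TrajectoryRecord] = []
        i = 0
        n = len(records)
        while i < n:
            a = records[i]
            # scan a run of records at one distinct location B directly after A
            j = i + 1
            loc_b = None
            while j < n:
                r = records[j]
                if (r.x, r.y) == (a.x, a.y):
                    break
                if loc_b is None:
                    loc_b = (r.x, r.y)
                elif (r.x, r.y) != loc_b:
                    break
                j += 1
            collapse = False
            if loc_b is not None and j < n and (records[j].x, records[j].y) == (a.x, a.y):
                dist = math.hypot(loc_b[0] - a.x, loc_b[1] - a.y)
                t_in = records[i + 1].abs_t - a.abs_t
                t_out = records[j].abs_t - records[j - 1].abs_t
                if dist <= max_jump_m and t_in <= window_s and t_out <= window_s:
                    collapse = True
            if collapse:
                out.append(a)  # middle B records dropped; the returning A kept next pass
                i = j
                changed = True
            else:
                out.append(a)
                i += 1
        records = out
    return Trajectory(user_id=traj.user_id, records=records)


def hourly_grid_times(days: int) -> list[tuple[int, int]]:
    """All (day, hour) pairs of the hourly target grid: 24 x days entries, ascending."""
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    return [(d, h) for d in range(1, days + 1) for h in range(24)]


def split_observed_hours(
    traj: Trajectory, snap_tol_s: float = 900.0, days: int | None = None
) -> tuple[list[tuple[int, int, float, float]], list[tuple[int, int]]]:
    """Partition the hourly grid into hours observed within tolerance and missing hours.

    An hour mark is observed iff at least one record lies within ``snap_tol_s``
    of it; the nearest such record supplies the location (tie broken toward
    the earlier record). ``days`` defaults to the trajectory's last day.
    """
    if snap_tol_s > 1800:
        raise ValueError("snap_tol_s must be <= 1800 (half an hour)")
    if days is None:
        days = max(traj.n_days, 1)
    grid = hourly_grid_times(days)
    observed: list[tuple[int, int, float, float]] = []
    missing: list[tuple[int, int]] = []
    recs = traj.records
    for day, hour in grid:
        mark = (day - 1) * SECONDS_PER_DAY + hour * 3600
        best = None  # (offset, order index)
        for idx, r in enumerate(recs):
            off = abs(r.abs_t - mark)
            if off <= snap_tol_s and (best is None or off < best[0]):
                best = (off, idx)
        if best is None:
            missing.append((day, hour))
        else:
            r = recs[best[1]]
            observed.append((day, hour, r.x, r.y))
    return observed, missing
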