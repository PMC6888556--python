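"""Seeded synthetic worlds: commuting agents, CDR-like sampling, known pollution fields.

Every stage of the pipeline is validated against ground truth that only a
generator can supply: agents follow anchor-structured daily schedules (home
overnight, a cluster-specific workplace by day, interpolated transit hours),
their traces are thinned to sparse event-driven records with a heavy-tailed
inter-event distribution, and the PM2.5 field is generated from the very
linear-in-meteorology model with spatially varying coefficients that the
estimation stage tries to recover, observed only at sparse station sites.
Everything is reproducible bit-for-bit from (seed, parameters).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pollution import Grid1km, MET_VARIABLES
from .trajectory_io import (
    ACTIVE_EVENT_TYPES,
    CDR_EVENT_TYPES,
    SECONDS_PER_DAY,
    Trajectory,
    TrajectoryRecord,
    hourly_grid_times,
)

_CDR_TYPES = tuple(sorted(CDR_EVENT_TYPES))
_ACTIVE_TYPES = tuple(sorted(ACTIVE_EVENT_TYPES))


@dataclass(frozen=True)
class EventModel:
    """Renewal-process model of record generation.

    Inter-event gaps are a Pareto/exponential mixture truncated to
    [min_gap_s, max_gap_s] — bursty short gaps with a heavy tail, as seen in
    call-detail-record data. Each event is a communication record (CDR) with
    probability ``cdr_share``, otherwise a network-generated record.
    """

    cdr_share: float = 0.34
    p_heavy: float = 0.4
    pareto_alpha: float = 1.5
    pareto_xm_s: float = 60.0
    exp_mean_s: float = 5400.0
    min_gap_s: float = 60.0
    max_gap_s: float = 43200.0


@dataclass
class Agent:
    user_id: str
    cluster: int
    home: tuple[float, float]
    work: tuple[float, float]
    true_hourly: list[tuple[int, int, float, float]]  # (day, hour, x, y)


# Daily schedule template: hour -> fraction of the home->work segment.
# Home overnight (20:00-08:00), work 09:00-17:00, transit in between.
_SCHEDULE_FRACTION = {h: 0.0 for h in range(8)}
_SCHEDULE_FRACTION[8] = 0.5
_SCHEDULE_FRACTION.update({h: 1.0 for h in range(9, 18)})
_SCHEDULE_FRACTION[18] = 2.0 / 3.0
_SCHEDULE_FRACTION[19] = 1.0 / 3.0
_SCHEDULE_FRACTION.update({h: 0.0 for h in range(20, 24)})


def generate_agents(
    n: int,
    n_clusters: int,
    grid: Grid1km,
    days: int = 2,
    seed: int = 0,
    jitter_m: float = 800.0,
    rng: np.random.Generator | None = None,
) -> list[Agent]:
    """Agents in movement-pattern clusters sharing a home/work schedule template.

    Each cluster owns a home base and a work base drawn apart from each other;
    agents jitter around their cluster's bases (Gaussian, ``jitter_m``), so
    within-cluster anchor sets overlap strongly and between-cluster sets do not.
    """
    if n < n_clusters:
        raise ValueError(f"n={n} < n_clusters={n_clusters}")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    width = grid.n_cols * grid.cell_m
    height = grid.n_rows * grid.cell_m
    margin = 0.1
    bases = []
    for _ in range(n_clusters):
        hx = grid.x0 + rng.uniform(margin, 1 - margin) * width
        hy = grid.y0 + rng.uniform(margin, 1 - margin) * height
        # workplace well away from home, kept inside the grid
        while True:
            wx = grid.x0 + rng.uniform(margin, 1 - margin) * width
            wy = grid.y0 + rng.uniform(margin, 1 - margin) * height
            if math.hypot(wx - hx, wy - hy) > 0.25 * min(width, height):
                break
        bases.append(((hx, hy), (wx, wy)))

    agents = []
    grid_times = hourly_grid_times(days)
    for i in range(n):
        cluster = i % n_clusters
        (hbx, hby), (wbx, wby) = bases[cluster]
        hx = hbx + rng.normal(0, jitter_m)
        hy = hby + rng.normal(0, jitter_m)
        wx = wbx + rng.normal(0, jitter_m)
        wy = wby + rng.normal(0, jitter_m)
        true_hourly = []
        for day, hour in grid_times:
            f = _SCHEDULE_FRACTION[hour]
            true_hourly.append((day, hour, hx + f * (wx - hx), hy + f * (wy - hy)))
        agents.append(Agent(user_id=f"agent{i:04d}", cluster=cluster,
                            home=(hx, hy), work=(wx, wy), true_hourly=true_hourly))
    return agents


def _position_at(agent: Agent, t_abs: float) -> tuple[float, float]:
    """Piecewise-constant occupancy: position of the hour containing t_abs."""
    idx = int(t_abs // 3600)
    idx = min(max(idx, 0), len(agent.true_hourly) - 1)
    _, _, x, y = agent.true_hourly[idx]
    return x, y


def sample_records(
    agent: Agent, model: EventModel, days: int, seed: int = 0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Thin an agent's true movement into sparse event-driven records.

    Events follow the renewal process of ``model``; each record takes the true
    position at its event time and an event-type label (CDR vs network-
    generated per ``cdr_share``).
    """
    if model.exp_mean_s <= 0 or model.pareto_xm_s <= 0:
        raise ValueError("event model rates must be positive")
    horizon = days * SECONDS_PER_DAY
    mean_gap = (model.p_heavy * model.pareto_alpha * model.pareto_xm_s
                / (model.pareto_alpha - 1.0)
                + (1 - model.p_heavy) * model.exp_mean_s)
    if horizon / mean_gap < 1:
        raise ValueError("event model implies an expected 0 records per day")
    rng = rng if rng is not None else np.random.default_rng(seed)
    t = rng.uniform(0, mean_gap)
    records = []
    while t < horizon:
        x, y = _position_at(agent, t)
        if rng.random() < model.cdr_share:
            ev = _CDR_TYPES[rng.integers(len(_CDR_TYPES))]
        else:
            ev = _ACTIVE_TYPES[rng.integers(len(_ACTIVE_TYPES))]
        day = int(t // SECONDS_PER_DAY) + 1
        records.append(TrajectoryRecord(
            user_id=agent.user_id, day=day, t=t - (day - 1) * SECONDS_PER_DAY,
            x=x, y=y, event_type=ev,
        ))
        if rng.random() < model.p_heavy:
            gap = model.pareto_xm_s * (1 + rng.pareto(model.pareto_alpha))
        else:
            gap = rng.exponential(model.exp_mean_s)
        t += float(np.clip(gap, model.min_gap_s, model.max_gap_s))
    return Trajectory(user_id=agent.user_id, records=records)


@dataclass(frozen=True)
class CoefficientSpec:
    """Smooth spatially varying coefficient fields for the linear PM model.

    beta1 (on visibility, ug/m3 per m) varies linearly west-east; the others
    are constant by default. Magnitudes give PM2.5 in the tens of ug/m3 over
    realistic covariate ranges.
    """

    beta0: float = 160.0  # polluted-episode background keeping PM positive region-wide
    beta1_base: float = -0.003
    beta1_gradient_per_m: float = -1.5e-7  # west-east drift of beta1 (3x contrast)
    beta2: float = -2.5  # wind speed, ug/m3 per (m/s)
    beta3: float = 0.6  # temperature, ug/m3 per degC


@dataclass(frozen=True)
class MetSpec:
    """Smooth covariate fields with diurnal cycles (visibility m, wind m/s, temp degC)."""

    vis_base: float = 6000.0
    vis_diurnal: float = 2000.0
    vis_gradient_per_m: float = 0.12  # ~4.8 km visibility span across a 40-km region
    vis_wave_amp: float = 900.0  # patchy haze structure, m
    vis_wave_length_m: float = 12000.0
    ws_base: float = 3.0
    ws_diurnal: float = 1.2
    ws_gradient_per_m: float = 8e-5  # ~3 m/s coast-to-inland span
    ws_wave_amp: float = 0.8  # terrain-channelled gust structure, m/s
    ws_wave_length_m: float = 15000.0
    tem_base: float = 8.0
    tem_diurnal: float = 5.0
    tem_gradient_per_m: float = 1.2e-4  # ~5 degC urban-rural span
    tem_wave_amp: float = 2.0  # urban-heat-island patches, degC
    tem_wave_length_m: float = 15000.0


def _met_fields(grid: Grid1km, spec: MetSpec, day: int, hour: int,
                coords: np.ndarray) -> dict[str, np.ndarray]:
    # Each variable combines a broad gradient with smooth shorter-wavelength
    # structure (patchy haze, channelled wind, heat-island pockets) at a
    # distinct wavelength and orientation: this is what keeps the three
    # covariates locally non-collinear and the local coefficients identifiable.
    xr = coords[:, 0] - grid.x0
    yr = coords[:, 1] - grid.y0
    cos_t = math.cos(2 * math.pi * (hour - 14) / 24.0)  # afternoon peak
    cos_w = math.cos(2 * math.pi * (hour - 16) / 24.0)
    kv = 2 * math.pi / spec.vis_wave_length_m
    kw = 2 * math.pi / spec.ws_wave_length_m
    kt = 2 * math.pi / spec.tem_wave_length_m
    return {
        "visibility": (spec.vis_base + spec.vis_gradient_per_m * xr
                       + spec.vis_wave_amp * np.sin(kv * xr + 0.7) * np.sin(kv * yr)
                       + spec.vis_diurnal * cos_t),
        "wind_speed": np.maximum(
            spec.ws_base + spec.ws_gradient_per_m * yr
            + spec.ws_wave_amp * np.cos(kw * xr) * np.sin(kw * yr + 1.3)
            + spec.ws_diurnal * cos_w, 0.1),
        "temperature": (spec.tem_base + spec.tem_gradient_per_m * (0.6 * xr + 0.4 * yr)
                        + spec.tem_wave_amp * np.sin(kt * xr) * np.cos(kt * yr)
                        + spec.tem_diurnal * cos_t),
    }


def beta_fields(grid: Grid1km, spec: CoefficientSpec) -> dict[str, np.ndarray]:
    """True coefficient value per cell (flat, row-major)."""
    coords = grid.cell_centers()
    xr = coords[:, 0] - grid.x0
    n = grid.n_cells
    return {
        "beta0": np.full(n, spec.beta0),
        "beta1": spec.beta1_base + spec.beta1_gradient_per_m * xr,
        "beta2": np.full(n, spec.beta2),
        "beta3": np.full(n, spec.beta3),
    }


def generate_field(
    grid: Grid1km,
    days: int = 2,
    coef_spec: CoefficientSpec = CoefficientSpec(),
    met_spec: MetSpec = MetSpec(),
    sigma: float = 5.0,
    n_pm_stations: int = 60,
    n_met_stations: int = 169,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[int, int], np.ndarray], pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """True hourly PM surfaces + station observations of PM and meteorology.

    PM per cell-hour = beta0 + beta1*VIS + beta2*WS + beta3*TEM + N(0, sigma).
    The world is cell-resolved, so stations sit at cell centers: pollution
    monitors occupy ``n_pm_stations`` seeded random cells and report their
    cell's (noisy) true value; weather stations form a regular lattice — a
    planned network — dense enough to resolve the covariate fields
    (``n_met_stations`` rounds down to the nearest feasible lattice).

    Returns (true_surfaces, pm_obs, met_obs, true_betas).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    betas = beta_fields(grid, coef_spec)
    centers = grid.cell_centers()
    pm_cells = rng.choice(grid.n_cells, size=min(n_pm_stations, grid.n_cells),
                          replace=False)
    pm_xy = centers[pm_cells]
    # regular lattice: smallest step whose station count fits n_met_stations
    step = 1
    while (len(range(step // 2, grid.n_rows, step))
           * len(range(step // 2, grid.n_cols, step))) > n_met_stations:
        step += 1
    met_cells = np.array([
        r * grid.n_cols + c
        for r in range(step // 2, grid.n_rows, step)
        for c in range(step // 2, grid.n_cols, step)
    ])
    met_xy = centers[met_cells]

    true_surfaces: dict[tuple[int, int], np.ndarray] = {}
    pm_rows, met_rows = [], []
    for day, hour in hourly_grid_times(days):
        met = _met_fields(grid, met_spec, day, hour, centers)
        pm = (betas["beta0"] + betas["beta1"] * met["visibility"]
              + betas["beta2"] * met["wind_speed"] + betas["beta3"] * met["temperature"])
        pm = pm + rng.normal(0, sigma, grid.n_cells) if sigma > 0 else pm
        pm = np.maximum(pm, 0.0)
        true_surfaces[(day, hour)] = pm
        for sid, (x, y), cell in zip(range(n_pm_stations), pm_xy, pm_cells):
            pm_rows.append({"station_id": f"pm{sid:03d}", "day": day, "hour": hour,
                            "x": x, "y": y, "pm": pm[cell]})
        met_at = _met_fields(grid, met_spec, day, hour, met_xy)
        for sid, (x, y) in enumerate(met_xy):
            met_rows.append({"station_id": f"met{sid:03d}", "day": day, "hour": hour,
                             "x": x, "y": y,
                             **{v: met_at[v][sid] for v in MET_VARIABLES}})
    return true_surfaces, pd.DataFrame(pm_rows), pd.DataFrame(met_rows), betas


@dataclass
class SyntheticWorld:
    seed: int
    days: int
    grid: Grid1km
    agents: list[Agent]
    trajectories: list[Trajectory]
    pm_obs: pd.DataFrame
    met_obs: pd.DataFrame
    true_surfaces: dict[tuple[int, int], np.ndarray]
    true_betas: dict[str, np.ndarray]
    sigma: float
    event_model: EventModel = field(default_factory=EventModel)

    def true_exposure(self, user_id: str) -> float:
        """Exact cumulative exposure from true trajectory x true surface."""
        agent = next(a for a in self.agents if a.user_id == user_id)
        total = 0.0
        for day, hour, x, y in agent.true_hourly:
            row, col, _ = self.grid.locate(x, y)
            total += float(self.true_surfaces[(day, hour)][self.grid.cell_id(row, col)])
        return total


def generate_world(
    seed: int = 0,
    n_agents: int = 200,
    n_clusters: int = 4,
    days: int = 2,
    grid: Grid1km | None = None,
    sigma: float = 5.0,
    n_pm_stations: int = 60,
    n_met_stations: int = 169,
    event_model: EventModel = EventModel(),
    coef_spec: CoefficientSpec = CoefficientSpec(),
    met_spec: MetSpec = MetSpec(),
    jitter_m: float = 800.0,
) -> SyntheticWorld:
    """Build the full default world (40x40 km grid, 200 agents, 4 clusters)."""
    if grid is None:
        grid = Grid1km(x0=0.0, y0=0.0, n_rows=40, n_cols=40)
    rng = np.random.default_rng([seed, 0])
    agents = generate_agents(n_agents, n_clusters, grid, days=days, rng=rng,
                             jitter_m=jitter_m)
    rng_rec = np.random.default_rng([seed, 1])
    trajectories = [sample_records(a, event_model, days, rng=rng_rec) for a in agents]
    rng_field = np.random.default_rng([seed, 2])
    surfaces, pm_obs, met_obs, betas = generate_field(
        grid, days=days, coef_spec=coef_spec, met_spec=met_spec, sigma=sigma,
        n_pm_stations=n_pm_stations, n_met_stations=n_met_stations, rng=rng_field,
    )
    return SyntheticWorld(seed=seed, days=days, grid=grid, agents=agents,
                          trajectories=trajectories, pm_obs=pm_obs, met_obs=met_obs,
                          true_surfaces=surfaces, true_betas=betas, sigma=sigma,
                          event_model=event_model)


def block_zones_geojson(grid: Grid1km, block_cells: int = 10) -> dict:
    """Subdistrict-like square zones of ``block_cells`` x ``block_cells`` grid cells."""
    features = []
    size = block_cells * grid.cell_m
    n_br = math.ceil(grid.n_rows / block_cells)
    n_bc = math.ceil(grid.n_cols / block_cells)
    for br in range(n_br):
        for bc in range(n_bc):
            x0 = grid.x0 + bc * size
            y0 = grid.y0 + br * size
            ring = [[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size],
                    [x0, y0]]
            features.append({
                "type": "Feature",
                "properties": {"zone_id": f"z{br:02d}_{bc:02d}"},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
    return {"type": "FeatureCollection", "features": features}


def world_zones(grid: Grid1km, block_cells: int = 10):
    """Subdistrict zones as shapely-backed Zone objects (10x10 km blocks)."""
    from shapely.geometry import shape

    from .anchors import Zone

    gj = block_zones_geojson(grid, block_cells)
    return [Zone(zone_id=f["properties"]["zone_id"], geometry=shape(f["geometry"]))
            for f in gj["features"]]


def write_world(world: SyntheticWorld, outdir) -> dict[str, str]:
    """Write the three input CSVs, zone GeoJSON and ground-truth tables to a directory."""
    from pathlib import Path

    from .trajectory_io import write_trajectories

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["traces"] = str(outdir / "traces.csv")
    write_trajectories(world.trajectories, paths["traces"])

    pm = world.pm_obs.copy()
    pm["time"] = pm["hour"].map(lambda h: f"{h:02d}:00")
    paths["pollution"] = str(outdir / "pollution.csv")
    pm.rename(columns={"pm": "pm25"})[
        ["station_id", "day", "time", "x", "y", "pm25"]
    ].to_csv(paths["pollution"], index=False)

    met = world.met_obs.copy()
    met["time"] = met["hour"].map(lambda h: f"{h:02d}:00")
    paths["meteorology"] = str(outdir / "meteorology.csv")
    met[["station_id", "day", "time", "x", "y", "wind_speed", "visibility",
         "temperature"]].to_csv(paths["meteorology"], index=False)

    paths["zones"] = str(outdir / "zones.geojson")
    with open(paths["zones"], "w") as fh:
        json.dump(block_zones_geojson(world.grid), fh)

    truth = pd.DataFrame([
        {"user_id": a.user_id, "cluster": a.cluster, "home_x": a.home[0],
         "home_y": a.home[1], "work_x": a.work[0], "work_y": a.work[1],
         "true_exposure": world.true_exposure(a.user_id)}
        for a in world.agents
    ])
    paths["truth"] = str(outdir / "ground_truth_agents.csv")
    truth.to_csv(paths["truth"], index=False)
    return paths
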