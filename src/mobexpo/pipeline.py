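"""End-to-end orchestration: traces + station data -> exposure estimates.

Stage order: preprocess and cluster users, fit per-cluster reconstruction
models and densify every trajectory to hourly resolution; krige meteorology
and fit per-hour GWR concentration surfaces; integrate trajectories against
surfaces into the three exposure estimates and their comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import anchors as anchors_mod
from . import exposure as exposure_mod
from . import reconstruction as recon_mod
from .mobility import MobilityFeatures, compute_features
from .pollution import Grid1km, PollutionSurface, fit_all_hours
from .trajectory_io import HourlyTrajectory, Trajectory, suppress_oscillation


@dataclass
class PipelineResult:
    features: dict[str, MobilityFeatures] = field(default_factory=dict)
    anchor_sets: list = field(default_factory=list)
    clustering: anchors_mod.UserClustering | None = None
    models: dict[int, recon_mod.TrajectoryReconstructor] = field(default_factory=dict)
    hourly: dict[str, HourlyTrajectory] = field(default_factory=dict)
    surface: PollutionSurface | None = None
    diagnostics: pd.DataFrame | None = None
    homes: dict[str, tuple[float, float]] = field(default_factory=dict)
    exposures: dict[str, dict[str, exposure_mod.ExposureSeries]] = field(default_factory=dict)
    recon_report: recon_mod.ReconstructionReport | None = None
    ks: dict[str, tuple[float, float]] = field(default_factory=dict)
    zone_summaries: list = field(default_factory=list)
    away_relation: tuple | None = None


def reconstruct_stage(
    trajectories: Sequence[Trajectory],
    seed: int = 0,
    n_clusters: int = 4,
    alpha_m: float = 500.0,
    beta: float = 0.2,
    linkage: str = "average",
    zones=None,
    grid: Grid1km | None = None,
    window_s: float = 300.0,
    max_jump_m: float = 2000.0,
    snap_tol_s: float = 900.0,
    days: int | None = None,
    resample_intervals: Sequence[float] = (3600.0, 7200.0, 10800.0),
    gbdt_params: dict | None = None,
    result: PipelineResult | None = None,
) -> PipelineResult:
    """Preprocess, cluster, train per-cluster models and densify to hourly."""
    res = result or PipelineResult()
    trajs = [suppress_oscillation(t, window_s, max_jump_m) for t in trajectories]
    res.features = {t.user_id: compute_features(t) for t in trajs}
    res.anchor_sets = []
    for t in trajs:
        aset = anchors_mod.detect_anchors(t, alpha_m=alpha_m, beta=beta)
        anchors_mod.project_anchors_to_zones(aset, zones=zones, grid=grid)
        res.anchor_sets.append(aset)
    res.clustering = anchors_mod.assign_clusters(res.anchor_sets, linkage=linkage,
                                                 n_clusters=n_clusters)
    cluster_of = res.clustering.labels
    res.models = recon_mod.fit_cluster_models(
        trajs, res.features, cluster_of, resample_intervals=resample_intervals,
        seed=seed, **(gbdt_params or {}),
    )
    if days is None:
        days = max(t.n_days for t in trajs)
    for t in trajs:
        model = res.models[cluster_of[t.user_id]]
        res.hourly[t.user_id] = recon_mod.reconstruct_hourly(
            t, model, res.features[t.user_id], snap_tol_s=snap_tol_s, days=days)
    res._trajs = trajs  # preprocessed traces, reused downstream
    res._days = days
    return res


def field_stage(
    pm_obs: pd.DataFrame,
    met_obs: pd.DataFrame,
    grid: Grid1km,
    result: PipelineResult | None = None,
    **gwr_kwargs,
) -> PipelineResult:
    """Hourly kriging + GWR concentration surfaces with diagnostics."""
    res = result or PipelineResult()
    res.surface, res.diagnostics = fit_all_hours(pm_obs, met_obs, grid, **gwr_kwargs)
    return res


def exposure_stage(
    result: PipelineResult,
    day_types: dict[int, str] | None = None,
    top_frac: float = 0.2,
    zones=None,
    snap_tol_s: float = 900.0,
) -> PipelineResult:
    """Three-way exposure estimates, K-S comparisons and zone aggregation."""
    if result.surface is None:
        raise ValueError("field stage must run before the exposure stage")
    trajs = result._trajs
    days = result._days
    grid = result.surface.grid
    for t in trajs:
        home, _ = exposure_mod.infer_home(t)
        result.homes[t.user_id] = home
        result.exposures[t.user_id] = exposure_mod.three_way_estimates(
            t, result.hourly[t.user_id], result.surface, home, days,
            snap_tol_s=snap_tol_s)
    tr = [e["tr"].cumulative for e in result.exposures.values()]
    rec = [e["rec"].cumulative for e in result.exposures.values()]
    sl = [e["sl"].cumulative for e in result.exposures.values()]
    result.ks = {
        "tr_vs_rec": exposure_mod.ks_compare(tr, rec),
        "tr_vs_sl": exposure_mod.ks_compare(tr, sl),
    }
    if len(result.exposures) >= 5:
        series = {u: e["tr"] for u, e in result.exposures.items()}
        result.zone_summaries = exposure_mod.high_exposure_zone_summary(
            series, result.homes, grid, zones=zones, top_frac=top_frac)
        if len(result.zone_summaries) >= 2:
            try:
                result.away_relation = exposure_mod.away_exposure_relation(
                    result.zone_summaries)
            except ValueError:
                result.away_relation = None
    return result


def run_pipeline(
    trajectories: Sequence[Trajectory],
    pm_obs: pd.DataFrame,
    met_obs: pd.DataFrame,
    grid: Grid1km,
    seed: int = 0,
    n_clusters: int = 4,
    zones=None,
    day_types: dict[int, str] | None = None,
    **stage_kwargs,
) -> PipelineResult:
    """All three stages in order on explicit inputs."""
    res = reconstruct_stage(trajectories, seed=seed, n_clusters=n_clusters,
                            zones=zones, grid=grid, **stage_kwargs)
    res = field_stage(pm_obs, met_obs, grid, result=res)
    return exposure_stage(res, day_types=day_types, zones=zones)
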