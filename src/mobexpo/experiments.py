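"""Seeded validation experiments on synthetic worlds.

Three study designs, each runnable end to end from a single seed:

- ``beta1_recovery``: can the hourly spatial regressions recover the true
  spatially varying visibility coefficient from noisy station data?
- ``reconstruction_ranking``: does the cluster-pooled boosted-tree
  reconstructor beat nearest/linear interpolation on records held out the way
  sparse traces are actually split (communication records kept, network-
  generated records hidden)?
- ``exposure_ranking``: is exposure estimated from reconstructed trajectories
  closer to ground truth than exposure from raw records or from a static home
  location?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import anchors as anchors_mod
from . import exposure as exposure_mod
from . import reconstruction as recon_mod
from .mobility import compute_features
from .pollution import (
    MET_VARIABLES,
    Grid1km,
    PollutionSurface,
    attach_covariates,
    fit_gwr_hour,
    krige_meteorology,
)
from .synthetic import SyntheticWorld, generate_field, generate_world, world_zones
from .trajectory_io import CDR_EVENT_TYPES, Trajectory


@dataclass
class Beta1Recovery:
    pearson_r: float
    mae: float
    mean_r2: float
    sigma: float
    n_stations: int


def beta1_recovery(
    sigma: float = 5.0,
    seed: int = 1,
    grid: Grid1km | None = None,
    bandwidth: int = 25,
    n_pm_stations: int = 60,
) -> Beta1Recovery:
    """Day-averaged recovery of the spatially varying visibility coefficient.

    One simulated day is generated at noise level ``sigma``; the 24 hourly
    models are fitted at a fixed adaptive bandwidth (a noise-ladder experiment
    holds the estimator fixed so differences reflect noise alone), and each
    station's fitted beta1 is averaged over the day — beta1 is time-invariant,
    so the day mean is its natural estimator.
    """
    if grid is None:
        grid = Grid1km(x0=0.0, y0=0.0, n_rows=40, n_cols=40)
    _, pm, met, betas = generate_field(grid, days=1, sigma=sigma, seed=seed,
                                       n_pm_stations=n_pm_stations)
    station0 = pm[pm.hour == 0][["x", "y"]].reset_index(drop=True)
    coords = station0.to_numpy()
    cells = [grid.cell_id(*grid.locate(x, y)[:2]) for x, y in coords]
    true_b1 = betas["beta1"][cells]
    b1_fits, r2s = [], []
    for hour in range(24):
        pm_h = pm[pm.hour == hour]
        met_h = met[met.hour == hour]
        surfaces = {
            v: krige_meteorology(met_h[["x", "y", v]].rename(columns={v: "value"}), grid)
            for v in MET_VARIABLES
        }
        cov, _ = attach_covariates(coords, grid, surfaces)
        rows = pd.concat([pm_h[["pm", "x", "y"]].reset_index(drop=True), cov], axis=1)
        model = fit_gwr_hour(rows, bandwidth=bandwidth, day=1, hour=hour)
        b1_fits.append(model.model.coef_[:, 1])
        r2s.append(model.r2)
    b1_mean = np.mean(b1_fits, axis=0)
    return Beta1Recovery(
        pearson_r=float(pearsonr(true_b1, b1_mean).statistic),
        mae=float(np.mean(np.abs(true_b1 - b1_mean))),
        mean_r2=float(np.mean(r2s)),
        sigma=sigma,
        n_stations=len(coords),
    )


def _split_world(world: SyntheticWorld) -> tuple[list[Trajectory], dict[str, list]]:
    """Per-user split: communication records kept, network-generated held out."""
    kept_trajs, held = [], {}
    for traj in world.trajectories:
        kept = [r for r in traj.records if r.event_type in CDR_EVENT_TYPES]
        hidden = [r for r in traj.records if r.event_type not in CDR_EVENT_TYPES]
        if len(kept) >= 3 and hidden:
            kept_trajs.append(Trajectory(user_id=traj.user_id, records=kept))
            held[traj.user_id] = hidden
    return kept_trajs, held


@dataclass
class ReconstructionRanking:
    mae: dict[str, float]
    stdev: dict[str, float]
    n_heldout: int


def reconstruction_ranking(
    seed: int = 1,
    world: SyntheticWorld | None = None,
    n_clusters: int = 4,
) -> ReconstructionRanking:
    """Held-out comparison of the boosted-tree reconstructor vs interpolation.

    Everything downstream of the split uses only the kept records: mobility
    features, anchor clustering, and model training — exactly the information
    available when the network-generated records are truly missing.
    """
    if world is None:
        world = generate_world(seed=seed)
    kept_trajs, _ = _split_world(world)
    features = {t.user_id: compute_features(t) for t in kept_trajs}
    anchor_sets = []
    for t in kept_trajs:
        aset = anchors_mod.detect_anchors(t)
        anchors_mod.project_anchors_to_zones(aset, zones=world_zones(world.grid))
        anchor_sets.append(aset)
    clustering = anchors_mod.assign_clusters(anchor_sets, n_clusters=n_clusters)
    models = recon_mod.fit_cluster_models(kept_trajs, features, clustering.labels,
                                          seed=seed)
    # evaluate_holdout re-applies the same event-type split to the full traces
    full = [t for t in world.trajectories if t.user_id in features]
    report = recon_mod.evaluate_holdout(full, features, clustering.labels, models,
                                        holdout_mode="event_type", seed=seed)
    return ReconstructionRanking(
        mae={m: e.mae for m, e in report.per_method.items()},
        stdev={m: e.stdev for m, e in report.per_method.items()},
        n_heldout=report.n_heldout,
    )


@dataclass
class ExposureRanking:
    median_abs_err: dict[str, float]
    ks: dict[str, tuple[float, float]]
    n_users: int


def exposure_ranking(
    seed: int = 1,
    world: SyntheticWorld | None = None,
    n_clusters: int = 4,
    surface: PollutionSurface | None = None,
) -> ExposureRanking:
    """Three-way exposure estimates vs exact ground-truth exposure.

    Ground truth integrates each agent's true hourly trajectory against the
    true (noisy) concentration field; the three estimators only see the
    sampled records and the station-estimated surfaces.
    """
    from .pipeline import exposure_stage, field_stage, reconstruct_stage

    if world is None:
        world = generate_world(seed=seed)
    zones = world_zones(world.grid)
    res = reconstruct_stage(world.trajectories, seed=seed, n_clusters=n_clusters,
                            zones=zones, days=world.days)
    if surface is None:
        res = field_stage(world.pm_obs, world.met_obs, world.grid, result=res)
    else:
        res.surface = surface
    res = exposure_stage(res, zones=zones)
    errs: dict[str, list[float]] = {"tr": [], "rec": [], "sl": []}
    for agent in world.agents:
        if agent.user_id not in res.exposures:
            continue
        truth = world.true_exposure(agent.user_id)
        for m in errs:
            errs[m].append(abs(res.exposures[agent.user_id][m].cumulative - truth))
    return ExposureRanking(
        median_abs_err={m: float(np.median(v)) for m, v in errs.items()},
        ks={k: v for k, v in res.ks.items()},
        n_users=len(errs["tr"]),
    )
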