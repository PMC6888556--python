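"""Anchor-point detection, zone projection, Jaccard similarity and user clustering.

An anchor is an area a user visits with at least a threshold share of their
records — typically the residence and workplace. Anchors are found by a greedy
merge: repeatedly take the unconsumed location with the most records, absorb
all unconsumed locations within a distance threshold alpha into one candidate
("examinee"), and finally keep candidates holding at least a fraction beta of
the user's records. Users are then compared by the Jaccard index of the zones
their anchors fall in, and grouped by agglomerative clustering so that a
reconstruction model can be trained per movement-pattern group instead of per
individual.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from shapely.geometry import Point, shape

from .trajectory_io import Trajectory


@dataclass(frozen=True)
class Anchor:
    cx: float  # record-count-weighted centroid, meters
    cy: float
    members: tuple[tuple[float, float], ...]  # merged distinct locations
    record_count: int


@dataclass
class AnchorSet:
    user_id: str
    anchors: list[Anchor]
    zone_ids: set = field(default_factory=set)
    total_records: int = 0


def detect_anchors(traj: Trajectory, alpha_m: float = 500.0, beta: float = 0.2) -> AnchorSet:
    """Greedy anchor detection on one user's records.

    Distinct locations are ranked by record count (ties broken by earliest
    first visit, then lexicographic location); the top unconsumed location
    absorbs all unconsumed locations within ``alpha_m``; candidates whose
    aggregated count reaches ``beta`` x total records become anchors.
    """
    if alpha_m <= 0:
        raise ValueError("alpha_m must be positive")
    if not (0 < beta < 1):
        raise ValueError("beta must be in (0, 1)")
    if not traj.records:
        raise ValueError(f"user {traj.user_id}: empty trajectory")

    counts: dict[tuple[float, float], int] = {}
    first_visit: dict[tuple[float, float], int] = {}
    for idx, r in enumerate(traj.records):
        loc = (r.x, r.y)
        counts[loc] = counts.get(loc, 0) + 1
        first_visit.setdefault(loc, idx)

    total = len(traj.records)
    consumed: set[tuple[float, float]] = set()
    examinees: list[tuple[list[tuple[float, float]], int]] = []
    order = sorted(counts, key=lambda loc: (-counts[loc], first_visit[loc], loc))
    for seed in order:
        if seed in consumed:
            continue
        members = [
            loc
            for loc in order
            if loc not in consumed and math.dist(seed, loc) <= alpha_m
        ]
        consumed.update(members)
        examinees.append((members, sum(counts[m] for m in members)))

    anchors = []
    for members, agg in examinees:
        if agg >= beta * total:
            w = np.array([counts[m] for m in members], dtype=float)
            pts = np.array(members, dtype=float)
            cx, cy = (pts * w[:, None]).sum(axis=0) / w.sum()
            anchors.append(
                Anchor(cx=float(cx), cy=float(cy), members=tuple(members), record_count=agg)
            )
    return AnchorSet(user_id=traj.user_id, anchors=anchors, total_records=total)


@dataclass
class Zone:
    zone_id: str
    geometry: object  # shapely geometry


def load_zones(path) -> list[Zone]:
    """Read zone polygons from a GeoJSON FeatureCollection with property ``zone_id``."""
    with open(path) as fh:
        gj = json.load(fh)
    zones = []
    for feat in gj.get("features", []):
        zid = feat.get("properties", {}).get("zone_id")
        if zid is None:
            raise ValueError("GeoJSON feature missing property 'zone_id'")
        zones.append(Zone(zone_id=str(zid), geometry=shape(feat["geometry"])))
    return zones


def grid_zone_id(x: float, y: float, grid) -> str:
    """Fallback zoning: the 1-km grid cell acts as the zone."""
    row, col, _ = grid.locate(x, y)
    return f"cell_{row}_{col}"


def project_anchors_to_zones(
    anchor_set: AnchorSet, zones: list[Zone] | None = None, grid=None
) -> AnchorSet:
    """Assign each anchor centroid to a zone; zone_ids becomes the set of hit zones.

    Boundary points go to the zone with the lowest zone_id. Without polygons a
    grid must be supplied and its cells act as zones.
    """
    if zones is None and grid is None:
        raise ValueError(
            "no zones supplied; pass GeoJSON zones or a Grid1km for grid-cell fallback zoning"
        )
    zone_ids = set()
    if zones is not None:
        ordered = sorted(zones, key=lambda z: z.zone_id)
        for a in anchor_set.anchors:
            pt = Point(a.cx, a.cy)
            for z in ordered:
                if z.geometry.covers(pt):
                    zone_ids.add(z.zone_id)
                    break
    else:
        for a in anchor_set.anchors:
            zone_ids.add(grid_zone_id(a.cx, a.cy, grid))
    anchor_set.zone_ids = zone_ids
    return anchor_set


def jaccard_similarity(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets give 0 by convention."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def similarity_matrix(anchor_sets: list[AnchorSet]) -> tuple[list[str], np.ndarray]:
    """Pairwise Jaccard similarity over zone-projected anchor sets; diagonal forced to 1."""
    users = [s.user_id for s in anchor_sets]
    n = len(users)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = jaccard_similarity(
                anchor_sets[i].zone_ids, anchor_sets[j].zone_ids
            )
    return users, sim


@dataclass
class UserClustering:
    labels: dict  # user_id -> cluster id (0-based, contiguous)
    similarity: np.ndarray
    linkage_record: np.ndarray


def cluster_users(
    users: list[str],
    similarity: np.ndarray,
    linkage: str = "average",
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
) -> UserClustering:
    """Agglomerative clustering of users on distance = 1 - Jaccard similarity.

    Exactly one of ``n_clusters`` / ``distance_threshold`` selects the cut.
    Deterministic given inputs.
    """
    sim = np.asarray(similarity, dtype=float)
    if sim.shape != (len(users), len(users)) or not np.allclose(sim, sim.T):
        raise ValueError("similarity must be a symmetric (n_users, n_users) matrix")
    if not np.allclose(np.diag(sim), 1.0):
        raise ValueError("similarity diagonal must be 1")
    if (n_clusters is None) == (distance_threshold is None):
        raise ValueError("specify exactly one of n_clusters or distance_threshold")

    if len(users) == 1:
        return UserClustering(labels={users[0]: 0}, similarity=sim, linkage_record=np.empty((0, 4)))

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = fcluster(Z, t=distance_threshold, criterion="distance")
    # relabel to 0-based ids ordered by first appearance
    remap: dict[int, int] = {}
    labels = {}
    for u, lab in zip(users, raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[u] = remap[lab]
    return UserClustering(labels=labels, similarity=sim, linkage_record=Z)


def assign_clusters(
    anchor_sets: list[AnchorSet],
    linkage: str = "average",
    n_clusters: int = 4,
) -> UserClustering:
    """Cluster users by anchor-zone similarity; anchorless users get singleton clusters.

    Users whose traces were too sparse to yield any anchor cannot be compared
    by Jaccard overlap, so rather than aborting, each is placed in its own
    fallback cluster after the main groups.
    """
    with_anchors = [s for s in anchor_sets if s.zone_ids]
    without = [s for s in anchor_sets if not s.zone_ids]
    if with_anchors:
        users, sim = similarity_matrix(with_anchors)
        k = min(n_clusters, len(users))
        clustering = cluster_users(users, sim, linkage=linkage, n_clusters=k)
    else:
        clustering = UserClustering(labels={}, similarity=np.empty((0, 0)),
                                    linkage_record=np.empty((0, 4)))
    next_id = max(clustering.labels.values(), default=-1) + 1
    for s in without:
        clustering.labels[s.user_id] = next_id
        next_id += 1
    return clustering
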