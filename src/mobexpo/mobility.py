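"""Per-user global movement descriptors: radius of gyration and location entropy.

Both are standard human-mobility summaries and enter the trajectory
reconstruction model as per-user features: the radius of gyration measures the
spatial extent of movement (root-mean-square distance of all records from
their barycenter), and the Shannon entropy of visit frequencies measures how
evenly time is spread over distinct locations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory_io import Trajectory


@dataclass(frozen=True)
class MobilityFeatures:
    user_id: str
    rog_m: float
    entropy_bits: float
    n_locations: int


def radius_of_gyration(records: Sequence[tuple[float, float]]) -> float:
    """RMS distance of all records (with multiplicity) from their barycenter, meters."""
    if len(records) == 0:
        raise ValueError("radius_of_gyration requires at least one record")
    pts = np.asarray(records, dtype=float)
    centroid = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))


def shannon_entropy(records: Sequence[tuple[float, float]]) -> float:
    """Entropy in bits of the visit-frequency distribution over distinct locations."""
    if len(records) == 0:
        raise ValueError("shannon_entropy requires at least one record")
    counts = np.array(list(Counter(map(tuple, records)).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def compute_features(traj: Trajectory) -> MobilityFeatures:
    pts = [(r.x, r.y) for r in traj.records]
    return MobilityFeatures(
        user_id=traj.user_id,
        rog_m=radius_of_gyration(pts),
        entropy_bits=shannon_entropy(pts),
        n_locations=len(set(pts)),
    )
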