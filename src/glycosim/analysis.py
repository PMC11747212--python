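"""k-th nearest-neighbor distance distributions of sialic-acid clouds.

The k-NN distance of a point is the Euclidean distance to its k-th closest
*other* point; the distribution over all points summarizes spatial
organization (intra-glycan pairs, glycan spacing on a protein, and protein
spacing each leave a characteristic peak).  Distances are computed with a
KD-tree in the cloud's native dimension; an xy-projection option is
available for comparing 3D simulations with 2D renderings.

Duplicate coordinates (e.g. several sialic acids of one glycolipid, which
all sit at the anchor) yield zero nearest-neighbor distances and are kept:
an experiment would localize each fluorophore separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .simulator import SiaCloud

__all__ = ["NNDistribution", "knn_distances", "summarize_by_condition"]


@dataclass
class NNDistribution:
    """k-th nearest-neighbor distances (microns), one per input point."""

    k: int
    distances: np.ndarray

    def __len__(self) -> int:
        return len(self.distances)

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def q1(self) -> float:
        return float(np.percentile(self.distances, 25))

    @property
    def q3(self) -> float:
        return float(np.percentile(self.distances, 75))

    @property
    def min(self) -> float:
        return float(np.min(self.distances))

    @property
    def max(self) -> float:
        return float(np.max(self.distances))

    def summary(self) -> dict:
        return {
            "n": len(self),
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "min": self.min,
            "max": self.max,
        }


def _positions(cloud) -> np.ndarray:
    if isinstance(cloud, SiaCloud):
        return cloud.positions
    return np.asarray(cloud, dtype=float)


def knn_distances(cloud, k: int = 1, project_xy: bool = False) -> NNDistribution:
    """Distance from every point to its k-th closest other point.

    ``cloud`` may be a :class:`~glycosim.simulator.SiaCloud` or a plain
    ``(n, dim)`` array.  ``project_xy`` drops the z-coordinate first.
    Quartile convention in the summary: linear interpolation.  Raises
    ``ValueError`` unless the cloud holds more than ``k`` points.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k!r}")
    pos = _positions(cloud)
    if project_xy and pos.shape[1] == 3:
        pos = pos[:, :2]
    if len(pos) <= k:
        raise ValueError(
            f"need more than k={k} points for a k-th nearest neighbor, got {len(pos)}"
        )
    tree = cKDTree(pos)
    dists, _ = tree.query(pos, k=k + 1)
    return NNDistribution(k=k, distances=np.ascontiguousarray(dists[:, k]))


def summarize_by_condition(results) -> pd.DataFrame:
    """Summary table over labeled NN distributions.

    ``results`` is an iterable of ``(condition_label, NNDistribution)``;
    entries sharing a label are pooled.  Returns one row per condition with
    n, median, Q1, Q3, min and max (quartiles by linear interpolation),
    in first-appearance order.
    """
    pooled: dict = {}
    order: list = []
    for label, dist in results:
        if label not in pooled:
            pooled[label] = []
            order.append(label)
        pooled[label].append(np.asarray(dist.distances, dtype=float))
    if not order:
        raise ValueError("results must be non-empty")
    rows = []
    for label in order:
        d = np.concatenate(pooled[label])
        rows.append(
            {
                "condition": label,
                "n": len(d),
                "median": np.median(d),
                "q1": np.percentile(d, 25),
                "q3": np.percentile(d, 75),
                "min": d.min(),
                "max": d.max(),
            }
        )
    return pd.DataFrame(rows)
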