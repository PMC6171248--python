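"""Agglomerative clustering of genome distance matrices with quality metrics.

Clustering uses the Lance-Williams agglomeration implemented by
:func:`scipy.cluster.hierarchy.linkage`; the ``ward`` method applied to a
distance matrix corresponds to the Ward.D2 update (squared distances inside
the recurrence), which is the variant used here even though Jaccard distances
are not Euclidean — the dendrogram is a descriptive device and its quality is
judged by the agglomerative coefficient and silhouettes, not by a Euclidean
embedding.

The agglomerative coefficient AC = 1 - mean(first-merge height / final-merge
height) over leaves lies in [0, 1]; values near 1 indicate clear cluster
structure.  Dendrograms are cut by undoing the last k-1 merges, which makes
successive partitions exactly nested.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .exceptions import ValidationError
from .orthology import _validate_distance_matrix

__all__ = [
    "LINKAGE_METHODS",
    "MergeTree",
    "hierarchical_cluster",
    "agglomerative_coefficient",
    "cut_dendrogram",
    "silhouette_values",
    "adjusted_rand_index",
]

LINKAGE_METHODS = ("ward", "average", "complete", "single")

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MergeTree:
    """Hierarchical clustering result: scipy linkage matrix + leaf labels."""

    linkage: np.ndarray
    labels: List[str]
    method: str

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage[:, :3], columns=["left", "right", "height"]
        ).assign(step=lambda d: d.index + 1)[["step", "left", "right", "height"]]


def hierarchical_cluster(dist: pd.DataFrame, method: str = "ward") -> MergeTree:
    """Agglomerative clustering of a square distance matrix."""
    if method not in LINKAGE_METHODS:
        raise ValidationError(f"method must be one of {LINKAGE_METHODS}")
    values = _validate_distance_matrix(dist)
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else [
        f"t{i}" for i in range(len(values))
    ]
    condensed = squareform(values, checks=False)
    Z = linkage(condensed, method=method)
    heights = Z[:, 2]
    if method == "ward" and np.any(np.diff(heights) < -1e-12):
        logger.info("Ward linkage produced %d height inversion(s)",
                    int(np.sum(np.diff(heights) < -1e-12)))
    return MergeTree(linkage=Z, labels=labels, method=method)


def agglomerative_coefficient(mt: MergeTree) -> float:
    """AC = 1 - mean over leaves of (first-merge height / final height)."""
    n = mt.n
    if n < 2:
        raise ValidationError("agglomerative coefficient needs >= 2 leaves")
    final = float(mt.linkage[-1, 2])
    if final <= 0:
        warnings.warn("all points identical: agglomerative coefficient set to 0")
        return 0.0
    first = np.full(n, np.nan)
    for row in mt.linkage:
        h = row[2]
        for side in (int(row[0]), int(row[1])):
            if side < n and np.isnan(first[side]):
                first[side] = h
    return float(1.0 - np.mean(first / final))


def cut_dendrogram(mt: MergeTree, k: int) -> pd.Series:
    """Partition into ``k`` clusters by undoing the last ``k - 1`` merges.

    Cluster labels 1..k are assigned in order of leaf appearance, so
    consecutive cuts are exactly nested (k+1 splits exactly one cluster of
    the k-cut).
    """
    n = mt.n
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}]")
    parent = list(range(n + max(n - k, 0)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        row = mt.linkage[step]
        new = n + step
        parent[find(int(row[0]))] = new
        parent[find(int(row[1]))] = new
    labels: Dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for leaf in range(n):
        root = find(leaf)
        if root not in labels:
            labels[root] = len(labels) + 1
        out[leaf] = labels[root]
    return pd.Series(out, index=mt.labels, name="cluster")


def _align_partition(dist_index, part: Mapping[str, int]) -> np.ndarray:
    part = pd.Series(part)
    if set(part.index) != set(dist_index):
        raise ValidationError("partition and matrix cover different genomes")
    return part.reindex(dist_index).to_numpy()


def silhouette_values(dist: pd.DataFrame, part: Mapping[str, int]) -> pd.Series:
    """Per-genome silhouette widths s(i) = (b - a) / max(a, b) in [-1, 1].

    ``a`` is the mean within-cluster distance to the other members and ``b``
    the smallest mean distance to another cluster; members of singleton
    clusters score 0 by convention.
    """
    values = _validate_distance_matrix(dist)
    labels = _align_partition(dist.index, part)
    k = len(np.unique(labels))
    if k < 2:
        raise ValidationError("silhouettes require at least 2 clusters")
    if k == len(labels):
        sil = np.zeros(len(labels))
    else:
        sil = silhouette_samples(values, labels, metric="precomputed")
    return pd.Series(sil, index=dist.index, name="silhouette")


def adjusted_rand_index(p1: Mapping[str, int], p2: Mapping[str, int]) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    s1, s2 = pd.Series(p1), pd.Series(p2)
    if set(s1.index) != set(s2.index):
        raise ValidationError("partitions cover different genomes")
    s2 = s2.reindex(s1.index)
    return float(adjusted_rand_score(s1.to_numpy(), s2.to_numpy()))
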