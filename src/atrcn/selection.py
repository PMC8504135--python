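"""Adaptive source-cohort selection by silhouette-guided k-means.

Cohorts are clustered in normalized descriptor space.  The number of
clusters k is chosen as the candidate in [ceil(N/4), floor(3N/4)] with the
largest mean silhouette coefficient (N = number of cohorts); the cohorts
sharing the target's cluster become the pre-training set.  Cluster
centroids can also be ranked by Euclidean distance from the target's
cluster, which orders alternative pre-training sets from most to least
similar.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .descriptors import DescriptorMatrix

logger = logging.getLogger("atrcn")


@dataclass
class ClusteringResult:
    k: int
    assignment: dict[str, int]        # cohort name -> cluster id in 1..k
    centroids: np.ndarray             # k x n_features
    silhouette_by_k: dict[int, float]
    seed: int

    def members(self, cluster_id: int) -> list[str]:
        return [c for c, g in self.assignment.items() if g == cluster_id]

    def to_json(self, path: str) -> None:
        payload = {
            "k": self.k,
            "assignment": self.assignment,
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "centroids": self.centroids.tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def candidate_k_range(n_cohorts: int) -> list[int]:
    """Integer ks in [ceil(N/4), floor(3N/4)], each raised to at least 2."""
    if n_cohorts < 4:
        raise ValueError("candidate k range requires at least 4 cohorts")
    lo = max(2, math.ceil(n_cohorts / 4))
    hi = math.floor(3 * n_cohorts / 4)
    if hi < lo:
        raise ValueError(f"empty candidate k range for N={n_cohorts}")
    return list(range(lo, hi + 1))


def choose_k_by_silhouette(
    d: DescriptorMatrix,
    ks: list[int] | None = None,
    seed: int = 0,
    n_init: int = 10,
) -> ClusteringResult:
    """Run k-means at each candidate k and keep the best-silhouette clustering.

    Exact silhouette ties break toward the smaller k (fewer clusters mean
    larger pre-training sets).  Deterministic given ``seed``.
    """
    x = d.normalized
    n = x.shape[0]
    if ks is None:
        ks = candidate_k_range(n)
    if not ks:
        raise ValueError("no candidate k values")
    if max(ks) >= n:
        raise ValueError(f"k={max(ks)} must be smaller than the number of cohorts ({n})")

    best: tuple[float, int] | None = None
    fits: dict[int, KMeans] = {}
    sil: dict[int, float] = {}
    for k in sorted(ks):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
        score = float(silhouette_score(x, labels, metric="euclidean"))
        fits[k] = km
        sil[k] = score
        if best is None or score > best[0]:
            best = (score, k)
    assert best is not None
    k = best[1]
    km = fits[k]
    assignment = {name: int(lbl) + 1 for name, lbl in zip(d.cohort_names, km.labels_)}
    return ClusteringResult(k, assignment, km.cluster_centers_.copy(), sil, seed)


def pretraining_set_for_target(c: ClusteringResult, target: str) -> list[str]:
    """Cohorts sharing the target's cluster, target excluded.

    A target alone in its cluster falls back to the members of the nearest
    other cluster (centroid Euclidean distance), with a warning.
    """
    if target not in c.assignment:
        raise KeyError(f"unknown target cohort {target!r}")
    own = c.assignment[target]
    mates = [name for name in c.members(own) if name != target]
    if mates:
        return mates
    ranked = rank_clusters_by_distance(c, target)
    for cluster_id, _dist in ranked:
        if cluster_id != own:
            logger.warning(
                "target %r is alone in cluster %d; falling back to nearest cluster %d",
                target, own, cluster_id,
            )
            return c.members(cluster_id)
    raise ValueError("no other cluster available for fallback")


def rank_clusters_by_distance(
    c: ClusteringResult, target: str
) -> list[tuple[int, float]]:
    """All clusters ordered by centroid distance from the target's cluster.

    The target's own cluster comes first with distance 0.
    """
    if target not in c.assignment:
        raise KeyError(f"unknown target cohort {target!r}")
    own = c.assignment[target]
    own_centroid = c.centroids[own - 1]
    dists = np.linalg.norm(c.centroids - own_centroid, axis=1)
    order = np.argsort(dists, kind="stable")
    return [(int(i) + 1, float(dists[i])) for i in order]
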