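"""Temporal-profile clustering with internal validation measures.

Each DE miRNA contributes a three-point profile of treated/control log2
ratios (0, 8, 120 h).  Profiles are centered and scaled per miRNA, then
clustered with several candidate algorithms (hierarchical with average,
complete and Ward linkage; k-means) over a range of cluster counts.
The winning (algorithm, k) is chosen by mean rank over three internal
validation measures:

* connectivity (lower is better): sum over points i and their L nearest
  neighbors j = 1..L of 1/j whenever the j-th neighbor falls outside
  i's cluster;
* Dunn index (higher): minimum inter-cluster point distance divided by
  the maximum intra-cluster diameter;
* mean silhouette width (higher), with silhouette 0 for singleton
  clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

ALGORITHMS = ("hierarchical-average", "hierarchical-complete", "hierarchical-ward", "kmeans")
_LINKAGE = {
    "hierarchical-average": "average",
    "hierarchical-complete": "complete",
    "hierarchical-ward": "ward",
}
DEFAULT_K_RANGE = tuple(range(2, 9))
CONNECTIVITY_NEIGHBORS = 10


def scale_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, sd 1 (ddof = 1).

    Constant rows become all-zero with a warning; missing values raise,
    naming the offending miRNA.
    """
    if profiles.isna().any().any():
        bad = profiles.index[profiles.isna().any(axis=1)][0]
        raise ValueError(f"profile {bad!r} is missing a time point")
    x = profiles.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant profile(s) scaled to zeros")
    sd[flat] = 1.0
    return pd.DataFrame((x - mean) / sd, index=profiles.index, columns=profiles.columns)


@dataclass
class ClusterSolution:
    """One clustering of the scaled profiles with its validation measures."""

    algorithm: str
    k: int
    assignment: pd.Series  # miRNA id -> cluster id in 1..k
    connectivity: float
    dunn: float
    silhouette: float

    @property
    def measures(self) -> tuple[float, float, float]:
        return (self.connectivity, self.dunn, self.silhouette)


def _assign(x: np.ndarray, algorithm: str, k: int) -> np.ndarray:
    if algorithm in _LINKAGE:
        z = linkage(x, method=_LINKAGE[algorithm])
        return fcluster(z, t=k, criterion="maxclust")
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=0)
        return km.fit_predict(x) + 1
    raise ValueError(f"unknown algorithm {algorithm!r}")


def cluster(profiles: pd.DataFrame, algorithm: str, k: int) -> ClusterSolution:
    """Cluster scaled profiles (Euclidean distance) into k groups."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(profiles)
    if k > n - 1:
        raise ValueError(f"k={k} too large for n={n} profiles")
    x = profiles.to_numpy(dtype=float)
    labels = _assign(x, algorithm, k)
    conn, dunn, sil = validation_measures(profiles, labels)
    return ClusterSolution(
        algorithm=algorithm,
        k=int(len(np.unique(labels))),
        assignment=pd.Series(labels, index=profiles.index, name="cluster"),
        connectivity=conn,
        dunn=dunn,
        silhouette=sil,
    )


def validation_measures(
    profiles: pd.DataFrame, assignment, n_neighbors: int = CONNECTIVITY_NEIGHBORS
) -> tuple[float, float, float]:
    """(connectivity, Dunn index, mean silhouette) of a partition."""
    x = profiles.to_numpy(dtype=float)
    labels = np.asarray(assignment)
    n = len(labels)
    dist = squareform(pdist(x))

    # connectivity: 1/j penalty whenever the j-th nearest neighbor of a
    # point lies outside its own cluster
    L = min(n_neighbors, n - 1)
    conn = 0.0
    order = np.argsort(dist + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    for i in range(n):
        for j in range(L):
            if labels[order[i, j]] != labels[i]:
                conn += 1.0 / (j + 1)

    # Dunn: min between-cluster distance / max within-cluster diameter
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    inter = dist[~same] if (~same).any() else np.array([np.inf])
    intra = dist[same & off_diag]
    max_diam = intra.max() if intra.size else 0.0
    dunn = float(inter.min() / max_diam) if max_diam > 0 else np.inf

    # silhouette with the singleton-cluster := 0 convention (as in
    # sklearn.silhouette_samples)
    if len(np.unique(labels)) < 2:
        sil = 0.0
    else:
        sil = float(silhouette_samples(x, labels).mean())
    return float(conn), dunn, sil


def select_solution(
    profiles: pd.DataFrame,
    algorithms=ALGORITHMS,
    k_range=DEFAULT_K_RANGE,
    n_neighbors: int = CONNECTIVITY_NEIGHBORS,
) -> ClusterSolution:
    """Evaluate every (algorithm, k) and pick the best mean validation rank.

    Connectivity is ranked ascending, Dunn and silhouette descending;
    ranks are averaged over the three measures and the smallest mean
    rank wins.  Ties go to the smaller k, then to the earlier algorithm
    in ``algorithms``.
    """
    solutions: list[ClusterSolution] = []
    for k in k_range:
        if k > len(profiles) - 1:
            continue
        for alg in algorithms:
            sol = cluster(profiles, alg, k)
            sol.connectivity, sol.dunn, sol.silhouette = validation_measures(
                profiles, sol.assignment.to_numpy(), n_neighbors=n_neighbors
            )
            solutions.append(sol)
    if not solutions:
        raise ValueError("no admissible (algorithm, k) combination")

    from scipy.stats import rankdata

    conn = rankdata([s.connectivity for s in solutions])
    dunn = rankdata([-s.dunn for s in solutions])
    sil = rankdata([-s.silhouette for s in solutions])
    mean_rank = (conn + dunn + sil) / 3.0
    alg_order = {a: i for i, a in enumerate(algorithms)}
    best = min(
        range(len(solutions)),
        key=lambda i: (mean_rank[i], solutions[i].k, alg_order[solutions[i].algorithm]),
    )
    return solutions[best]


def cluster_mean_profiles(profiles: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Per-cluster mean scaled profile (for plotting the temporal shapes)."""
    return profiles.groupby(assignment).mean()
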