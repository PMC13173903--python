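"""Per-sample, per-phase graph clustering with Davies-Bouldin resolution search.

Communities are found by modularity optimisation (Louvain by default, Leiden
optional) on the SNN graph at every resolution of the published grid
(0.01..0.1 step 0.01 and 0.2..1.0 step 0.05). Among resolutions producing
3-8 clusters the one minimising a medoid-based Davies-Bouldin index on the
1 - similarity distance matrix is selected (ties go to the lowest
resolution); if no resolution is feasible, the closest cluster count wins
with a warning.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd

from .preprocess import SnnGraph

__all__ = [
    "InitialClusterLabeling",
    "default_resolution_grid",
    "davies_bouldin",
    "select_resolution",
    "cluster_all",
]

MIN_CLUSTERS = 3
MAX_CLUSTERS = 8


@dataclass
class InitialClusterLabeling:
    sample_id: str
    phase: str
    labels: pd.Series           # per-cell dense cluster ids 0..n-1
    resolution: float
    db_index: float
    n_clusters: int
    grid_results: pd.DataFrame = field(default_factory=pd.DataFrame)


def default_resolution_grid() -> np.ndarray:
    fine = np.round(np.arange(0.01, 0.101, 0.01), 2)
    coarse = np.round(np.arange(0.20, 1.001, 0.05), 2)
    return np.concatenate([fine, coarse])


def _medoid(dist: np.ndarray, members: np.ndarray) -> int:
    """Cluster medoid: member minimising total intra-cluster distance.

    Exact ties are broken by the smaller total distance to the full dataset,
    then by index, so the choice is deterministic on degenerate clusters.
    """
    sub = dist[np.ix_(members, members)]
    intra = sub.sum(axis=1)
    best = np.flatnonzero(np.isclose(intra, intra.min()))
    if len(best) > 1:
        overall = dist[members[best]].sum(axis=1)
        best = best[np.flatnonzero(np.isclose(overall, overall.min()))]
    return int(members[best[0]])


def davies_bouldin(dist: np.ndarray, labels: np.ndarray) -> float:
    """Medoid-based Davies-Bouldin index on a precomputed distance matrix.

    scatter_i = mean distance of cluster members to the cluster medoid
    (medoid included); the index averages, over clusters, the worst
    (scatter_i + scatter_j) / d(medoid_i, medoid_j). Lower is better.
    Coincident medoids of distinct clusters make the pair infinitely bad.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("davies_bouldin needs at least 2 clusters")

    medoids, scatters = [], []
    for lab in uniq:
        members = np.flatnonzero(labels == lab)
        med = _medoid(dist, members)
        medoids.append(med)
        scatters.append(dist[members, med].mean())

    k = len(uniq)
    worst = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            sep = dist[medoids[i], medoids[j]]
            if sep <= 0:
                warnings.warn("coincident medoids of distinct clusters", stacklevel=2)
                ratio = np.inf
            else:
                ratio = (scatters[i] + scatters[j]) / sep
            worst[i] = max(worst[i], ratio)
    return float(worst.mean())


def _snn_to_igraph(g: SnnGraph) -> igraph.Graph:
    coo = g.similarity.tocoo()
    mask = (coo.row < coo.col) & (coo.data > 0)
    edges = list(zip(coo.row[mask].tolist(), coo.col[mask].tolist()))
    graph = igraph.Graph(n=g.similarity.shape[0], edges=edges)
    graph.es["weight"] = coo.data[mask].tolist()
    return graph


def _communities(graph: igraph.Graph, resolution: float, method: str, seed: int) -> np.ndarray:
    if method == "louvain":
        state = random.Random(seed)
        igraph.set_random_number_generator(state)
        try:
            part = graph.community_multilevel(weights="weight", resolution=resolution)
        finally:
            igraph.set_random_number_generator(random)
        return np.asarray(part.membership)
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        return np.asarray(part.membership)
    raise ValueError(f"unknown community detection method: {method}")


def _densify(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..n-1 by decreasing size (ties by old label)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.vectorize(remap.get)(labels)


def select_resolution(
    g: SnnGraph,
    grid: np.ndarray | None = None,
    method: str = "louvain",
    seed: int = 0,
    sample_id: str = "sample",
    phase: str = "G1",
    similarity_as_distance: bool = False,
) -> InitialClusterLabeling:
    """Pick the grid resolution minimising the Davies-Bouldin index.

    Only resolutions yielding 3-8 clusters compete; ties favour the lowest
    resolution. With no feasible resolution, the grid point whose cluster
    count is nearest the 3-8 range is returned with a warning.
    ``similarity_as_distance`` feeds the scaled similarity matrix directly to
    the index (the literal published wording) instead of 1 - similarity.
    """
    if grid is None:
        grid = default_resolution_grid()
    graph = _snn_to_igraph(g)
    if similarity_as_distance:
        dist = np.asarray(g.similarity.todense())
        np.fill_diagonal(dist, 0.0)
    else:
        dist = g.distance()

    rows = []
    best = None
    for res in grid:
        labels = _communities(graph, float(res), method, seed)
        n_clust = len(np.unique(labels))
        feasible = MIN_CLUSTERS <= n_clust <= MAX_CLUSTERS
        db = davies_bouldin(dist, labels) if n_clust >= 2 else np.nan
        rows.append({"resolution": float(res), "n_clusters": n_clust,
                     "db_index": db, "feasible": feasible})
        if feasible and (best is None or db < best["db_index"] - 1e-12):
            best = {"resolution": float(res), "labels": labels,
                    "db_index": db, "n_clusters": n_clust}

    grid_df = pd.DataFrame(rows)
    if best is None:
        warnings.warn(
            f"{sample_id}/{phase}: no resolution yields {MIN_CLUSTERS}-{MAX_CLUSTERS} "
            "clusters; falling back to the nearest cluster count",
            stacklevel=2,
        )
        dist_to_range = grid_df["n_clusters"].apply(
            lambda n: max(MIN_CLUSTERS - n, n - MAX_CLUSTERS, 0)
        )
        i = int(dist_to_range.idxmin())
        res = float(grid_df.loc[i, "resolution"])
        labels = _communities(graph, res, method, seed)
        best = {
            "resolution": res,
            "labels": labels,
            "db_index": float(grid_df.loc[i, "db_index"]),
            "n_clusters": int(grid_df.loc[i, "n_clusters"]),
        }

    return InitialClusterLabeling(
        sample_id=sample_id,
        phase=phase,
        labels=pd.Series(_densify(best["labels"]), index=g.cells, name="cluster"),
        resolution=best["resolution"],
        db_index=float(best["db_index"]),
        n_clusters=best["n_clusters"],
        grid_results=grid_df,
    )


def cluster_all(
    graphs: dict[tuple[str, str], SnnGraph],
    grid: np.ndarray | None = None,
    method: str = "louvain",
    seed: int = 0,
    min_cells: int = 50,
) -> list[InitialClusterLabeling]:
    """One labeling per (sample, phase) stratum with at least ``min_cells``."""
    out = []
    for (sample_id, phase), g in sorted(graphs.items()):
        n = g.similarity.shape[0]
        if n < min_cells:
            warnings.warn(
                f"skipping {sample_id}/{phase}: only {n} cells (< {min_cells})",
                stacklevel=2,
            )
            continue
        out.append(
            select_resolution(
                g, grid=grid, method=method, seed=seed, sample_id=sample_id, phase=phase
            )
        )
    return out
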