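"""Merge per-sample initial clusters into meta clusters shared across samples.

Cluster mean profiles over the shared HVG set (genes variable in >= 3
samples) are compared by Spearman correlation; average-linkage hierarchical
clustering on 1 - rho cut at height 1 - cutoff (default cutoff 0.75 on the
similarity scale) defines the meta clusters, which are renamed MC0.. by
decreasing total cell count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .clustering import InitialClusterLabeling

__all__ = [
    "SharedHvgSet",
    "MetaClusterAssignment",
    "shared_hvgs",
    "cluster_profiles",
    "intercluster_similarity",
    "cut_meta_clusters",
]

ClusterKey = tuple[str, str, int]  # (sample_id, phase, cluster)


@dataclass
class SharedHvgSet:
    genes: list[str]
    support: pd.Series  # per-gene count of samples where variable


@dataclass
class MetaClusterAssignment:
    mapping: dict[ClusterKey, str]    # initial cluster -> "MC0", "MC1", ...
    heights: np.ndarray               # linkage merge heights
    linkage: np.ndarray
    newick: str

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "phase": p, "cluster": c, "mc": mc}
            for (s, p, c), mc in sorted(self.mapping.items())
        ]
        return pd.DataFrame(rows)


def shared_hvgs(hvg_lists: dict[str, list[str]], min_support: int = 3) -> SharedHvgSet:
    """Genes flagged variable in at least ``min_support`` samples."""
    if len(hvg_lists) < min_support:
        raise ValueError(
            f"need >= {min_support} samples with HVG lists, got {len(hvg_lists)}"
        )
    support: dict[str, int] = {}
    for genes in hvg_lists.values():
        for g in set(genes):
            support[g] = support.get(g, 0) + 1
    sup = pd.Series(support, name="support").sort_index()
    keep = sup[sup >= min_support]
    if keep.empty:
        raise ValueError(
            f"no gene is variable in >= {min_support} samples; lower min_support"
        )
    return SharedHvgSet(genes=list(keep.index), support=keep)


def cluster_profiles(
    lognorm_by_sample: dict[tuple[str, str], pd.DataFrame],
    labelings: list[InitialClusterLabeling],
    genes: list[str],
    min_cells: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean log-normalised expression per initial cluster over ``genes``.

    Returns (profiles indexed by "sample|phase|cluster", cluster cell counts).
    Clusters with fewer than ``min_cells`` cells are excluded with a warning.
    """
    rows, sizes, index = [], [], []
    for lab in labelings:
        expr = lognorm_by_sample[(lab.sample_id, lab.phase)]
        use = [g for g in genes if g in expr.columns]
        for cl in sorted(lab.labels.unique()):
            cells = lab.labels.index[lab.labels == cl]
            if len(cells) < min_cells:
                warnings.warn(
                    f"{lab.sample_id}/{lab.phase} cluster {cl}: "
                    f"{len(cells)} cells < {min_cells}; excluded",
                    stacklevel=2,
                )
                continue
            rows.append(expr.loc[cells, use].mean(axis=0).to_numpy())
            sizes.append(len(cells))
            index.append(f"{lab.sample_id}|{lab.phase}|{cl}")
    if not rows:
        raise ValueError("no initial cluster passed the size filter")
    profiles = pd.DataFrame(np.vstack(rows), index=index, columns=use)
    return profiles, pd.Series(sizes, index=index, name="n_cells")


def intercluster_similarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho between cluster profiles (average-rank ties)."""
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    constant = profiles.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profile(s); their correlations set to 0",
            stacklevel=2,
        )
    # rank per profile (average ties), then Pearson of ranks; this stays
    # well-defined profile-by-profile when some profile is constant
    ranks = rankdata(profiles.to_numpy(dtype=float), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=profiles.index, columns=profiles.index)


def _tree_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    tree = to_tree(linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id].replace(" ", "_")
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6f}"

    return rec(tree) + ";"


def cut_meta_clusters(
    sim: pd.DataFrame,
    cutoff: float = 0.75,
    sizes: pd.Series | None = None,
) -> MetaClusterAssignment:
    """Average-linkage cut of the similarity matrix at rho >= ``cutoff``.

    Distance is 1 - rho; the dendrogram is cut at height 1 - cutoff so that
    clusters merged while still >= cutoff-similar share a meta cluster.
    MC ids are assigned by decreasing total cell count (``sizes``; falls back
    to the number of member clusters).
    """
    names = list(sim.index)
    if len(names) == 1:
        key = _parse_key(names[0])
        return MetaClusterAssignment(
            mapping={key: "MC0"}, heights=np.array([]), linkage=np.empty((0, 4)),
            newick=f"{names[0]};",
        )
    d = 1.0 - sim.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = average(squareform(d, checks=False))
    flat = fcluster(link, t=1.0 - cutoff, criterion="distance")

    weight = sizes.reindex(names).fillna(1.0) if sizes is not None else pd.Series(1.0, index=names)
    totals = pd.Series(weight.to_numpy(), index=flat).groupby(level=0).sum()
    order = totals.sort_values(ascending=False, kind="stable").index
    rename = {old: f"MC{rank}" for rank, old in enumerate(order)}

    mapping = {_parse_key(nm): rename[fl] for nm, fl in zip(names, flat)}
    return MetaClusterAssignment(
        mapping=mapping,
        heights=link[:, 2].copy(),
        linkage=link,
        newick=_tree_newick(link, names),
    )


def _parse_key(name: str) -> ClusterKey:
    sample_id, phase, cluster = name.split("|")
    return sample_id, phase, int(cluster)
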