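"""Normalisation, cell-cycle phase assignment, PCA elbow and SNN graph.

Counts are variance-stabilised as regularised negative-binomial Pearson
residuals; the four standard per-cell covariates (mito fraction, RPL
fraction, genes detected, UMI total) are then regressed out of the residual
matrix. A log-normalised layer is kept for profile averaging. Phase scores
follow the expression-matched control-bin scheme (25 bins, 50 controls per
gene); a cell is S/G2M when either score is positive. The PCA elbow is the
first component after which the percent variance drop falls below 0.1
percentage points. The SNN graph is the Jaccard overlap of k-NN lists,
min-max scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NormalizedMatrix",
    "PhaseAssignment",
    "SnnGraph",
    "compute_covariates",
    "normalize",
    "assign_phase",
    "pca_elbow",
    "build_snn",
]


@dataclass
class NormalizedMatrix:
    """Pearson-residual matrix with a parallel log-normalised layer."""

    residuals: np.ndarray          # cells x genes, covariate-adjusted
    lognorm: sp.csr_matrix         # cells x genes, log1p(CP10K)
    genes: pd.Index
    cells: pd.Index
    hvg: list[str]
    residual_variance: pd.Series

    def hvg_residuals(self) -> np.ndarray:
        cols = self.genes.get_indexer(self.hvg)
        return self.residuals[:, cols]

    def lognorm_df(self, genes: list[str] | None = None) -> pd.DataFrame:
        x = np.asarray(self.lognorm.todense())
        df = pd.DataFrame(x, index=self.cells, columns=self.genes)
        return df if genes is None else df[genes]


@dataclass
class PhaseAssignment:
    s_score: pd.Series
    g2m_score: pd.Series
    phase: pd.Series  # "G1" or "S/G2M"


@dataclass
class SnnGraph:
    similarity: sp.csr_matrix  # cells x cells in [0, 1], symmetric, diag 1
    n_pcs: int
    cells: pd.Index

    def distance(self) -> np.ndarray:
        """Dense 1 - similarity matrix (zero diagonal)."""
        d = 1.0 - np.asarray(self.similarity.todense())
        np.fill_diagonal(d, 0.0)
        return d


def compute_covariates(
    m: ad.AnnData, mito_prefix: str = "MT-", rpl_prefix: str = "RPL"
) -> pd.DataFrame:
    """Per-cell pct_mito, pct_rpl, n_genes and n_umi from raw counts."""
    x = sp.csr_matrix(m.X)
    total = np.maximum(np.asarray(x.sum(axis=1)).ravel(), 1.0)
    names = m.var_names.astype(str)
    mito = np.asarray(names.str.startswith(mito_prefix) | names.str.contains(f"_{mito_prefix}", regex=False))
    rpl = np.asarray(names.str.startswith(rpl_prefix) | names.str.contains(f"_{rpl_prefix}", regex=False))
    return pd.DataFrame(
        {
            "pct_mito": np.asarray(x[:, mito].sum(axis=1)).ravel() / total if mito.any() else 0.0,
            "pct_rpl": np.asarray(x[:, rpl].sum(axis=1)).ravel() / total if rpl.any() else 0.0,
            "n_genes": np.asarray((x > 0).sum(axis=1)).ravel().astype(float),
            "n_umi": total,
        },
        index=m.obs_names,
    )


def _pearson_residuals(x: np.ndarray, theta: float, clip: float | None) -> np.ndarray:
    """Analytic NB Pearson residuals of a count matrix (cells x genes)."""
    total = x.sum(axis=1, keepdims=True)
    gene_sum = x.sum(axis=0, keepdims=True)
    mu = total * gene_sum / max(x.sum(), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x - mu) / np.sqrt(mu + mu ** 2 / theta)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    if clip is None:
        clip = np.sqrt(x.shape[0])
    return np.clip(r, -clip, clip)


def normalize(
    m: ad.AnnData,
    covariates: pd.DataFrame | None = None,
    n_hvg: int = 3000,
    theta: float = 100.0,
    target_sum: float = 1e4,
) -> NormalizedMatrix:
    """Variance-stabilise counts and regress out the per-cell covariates.

    Genes with zero counts everywhere are excluded before fitting. HVGs are
    the ``n_hvg`` genes with the largest residual variance (computed before
    covariate adjustment, so selection reflects biological dispersion).
    """
    x = np.asarray(sp.csr_matrix(m.X).todense(), dtype=float)
    nonzero = x.sum(axis=0) > 0
    x = x[:, nonzero]
    genes = m.var_names[nonzero]

    resid = _pearson_residuals(x, theta=theta, clip=None)
    res_var = pd.Series(resid.var(axis=0, ddof=1), index=genes)

    if covariates is None:
        covariates = compute_covariates(m)
    c = covariates.loc[m.obs_names, ["pct_mito", "pct_rpl", "n_genes", "n_umi"]].to_numpy(dtype=float)
    c = (c - c.mean(axis=0)) / np.where(c.std(axis=0) > 0, c.std(axis=0), 1.0)
    design = np.column_stack([np.ones(len(c)), c])
    beta, *_ = np.linalg.lstsq(design, resid, rcond=None)
    resid = resid - design @ beta

    n_hvg = min(n_hvg, len(genes))
    hvg = list(res_var.sort_values(ascending=False).index[:n_hvg])

    lib = np.maximum(x.sum(axis=1, keepdims=True), 1.0)
    lognorm = sp.csr_matrix(np.log1p(x / lib * target_sum))

    return NormalizedMatrix(
        residuals=resid,
        lognorm=lognorm,
        genes=pd.Index(genes),
        cells=m.obs_names.copy(),
        hvg=hvg,
        residual_variance=res_var,
    )


def assign_phase(
    nm: NormalizedMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> PhaseAssignment:
    """Score S and G2M programmes against expression-matched controls.

    Phase is S/G2M iff max(s_score, g2m_score) > 0, else G1.
    """
    s_use = [g for g in s_genes if g in nm.genes]
    g2m_use = [g for g in g2m_genes if g in nm.genes]
    if not s_use:
        raise ValueError("no S-phase genes present in the gene universe")
    if not g2m_use:
        raise ValueError("no G2M-phase genes present in the gene universe")

    adata = ad.AnnData(
        X=nm.lognorm.copy(),
        obs=pd.DataFrame(index=nm.cells),
        var=pd.DataFrame(index=nm.genes),
    )
    sc.tl.score_genes(adata, s_use, score_name="s_score", ctrl_size=ctrl_size,
                      n_bins=n_bins, random_state=seed)
    sc.tl.score_genes(adata, g2m_use, score_name="g2m_score", ctrl_size=ctrl_size,
                      n_bins=n_bins, random_state=seed)
    s = adata.obs["s_score"]
    g2m = adata.obs["g2m_score"]
    phase = pd.Series(
        np.where(np.maximum(s, g2m) > 0, "S/G2M", "G1"), index=nm.cells, name="phase"
    )
    return PhaseAssignment(s_score=s, g2m_score=g2m, phase=phase)


def pca_elbow(
    nm: NormalizedMatrix, max_pc: int = 100, seed: int = 0
) -> tuple[int, np.ndarray, np.ndarray]:
    """PCA on HVG residuals; elbow by the <0.1-percentage-point drop rule.

    Returns (n_pcs, cell embeddings for the first n_pcs, percent variance).
    """
    x = nm.hvg_residuals()
    max_pc = min(max_pc, min(x.shape) - 1)
    if max_pc < 3:
        raise ValueError("fewer than 3 principal components computable")
    pca = PCA(n_components=max_pc, svd_solver="full" if min(x.shape) < 1000 else "randomized",
              random_state=seed)
    emb = pca.fit_transform(x)
    var_pct = pca.explained_variance_ratio_ * 100.0

    drops = var_pct[:-1] - var_pct[1:]
    below = np.flatnonzero(drops < 0.1)
    if len(below):
        n_pcs = int(below[0]) + 1
    else:
        warnings.warn("variance drop never fell below 0.1%; using max_pc", stacklevel=2)
        n_pcs = max_pc
    return n_pcs, emb[:, : max(n_pcs, 2)], var_pct


def elbow_from_variance(var_pct: np.ndarray) -> int:
    """Elbow rule on a precomputed percent-variance vector (1-based index)."""
    var_pct = np.asarray(var_pct, dtype=float)
    drops = var_pct[:-1] - var_pct[1:]
    below = np.flatnonzero(drops < 0.1)
    return int(below[0]) + 1 if len(below) else len(var_pct)


def build_snn(pcs: np.ndarray, k: int = 20, cells: pd.Index | None = None) -> SnnGraph:
    """Shared-nearest-neighbour graph from a PC embedding.

    Neighbour lists (each cell's k nearest, self included) are compared by
    Jaccard overlap; the resulting similarities are min-max scaled to [0, 1].
    """
    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    if pcs.ndim != 2 or pcs.shape[1] < 2:
        raise ValueError("pcs must be a cell x n_pcs matrix with n_pcs >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    adj.data[:] = 1.0
    shared = (adj @ adj.T).tocoo()
    union = 2 * k - shared.data
    jacc = sp.csr_matrix((shared.data / union, (shared.row, shared.col)), shape=(n, n))

    mx = jacc.data.max() if jacc.nnz else 1.0
    mn = 0.0  # absent pairs share no neighbours
    if mx > mn:
        jacc.data = (jacc.data - mn) / (mx - mn)
    sim = jacc.maximum(jacc.T)
    sim.setdiag(1.0)
    return SnnGraph(similarity=sim.tocsr(), n_pcs=pcs.shape[1],
                    cells=cells if cells is not None else pd.RangeIndex(n))
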