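"""Species assignment, density-derived QC gates, mito filter and doublet consensus.

Species thresholds are the 10th percentile (linear-interpolation quantile) of
each species' UMI counts over the cells where that species dominates; a
nucleus is kept as human only if it clears the human threshold, stays below
the mouse threshold and has more human than mouse UMIs. Read/UMI gates come
from local minima of a Gaussian KDE of log10 counts. Doublets flagged by both
of two external methods are removed, capped at the expected multiplet count
ranked by the primary method's score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "SpeciesThresholds",
    "QcGates",
    "DoubletInputs",
    "call_species",
    "density_gates",
    "consensus_doublets",
    "apply_qc",
    "mito_mask",
]


@dataclass(frozen=True)
class SpeciesThresholds:
    t_human: float
    t_mouse: float


@dataclass(frozen=True)
class QcGates:
    umi_low: float
    umi_high: float
    reads_low: float = -np.inf
    reads_high: float = np.inf
    mito_max: float = 0.05

    def __post_init__(self) -> None:
        if self.umi_low > self.umi_high or self.reads_low > self.reads_high:
            raise ValueError("low gate must not exceed high gate")
        if not 0.0 < self.mito_max <= 1.0:
            raise ValueError("mito_max must lie in (0, 1]")


@dataclass
class DoubletInputs:
    barcodes: list[str]
    scores_primary: np.ndarray
    calls_primary: np.ndarray
    calls_secondary: np.ndarray
    n_expected: int

    def __post_init__(self) -> None:
        n = len(self.barcodes)
        self.scores_primary = np.asarray(self.scores_primary, dtype=float)
        self.calls_primary = np.asarray(self.calls_primary, dtype=bool)
        self.calls_secondary = np.asarray(self.calls_secondary, dtype=bool)
        if not (len(self.scores_primary) == len(self.calls_primary) == len(self.calls_secondary) == n):
            raise ValueError("doublet vectors must align with barcodes")
        if not np.all(np.isfinite(self.scores_primary)):
            raise ValueError("scores_primary must be finite")
        if self.n_expected < 0:
            raise ValueError("n_expected must be >= 0")


def call_species(
    human_umi: np.ndarray, mouse_umi: np.ndarray
) -> tuple[np.ndarray, SpeciesThresholds]:
    """Label each nucleus human or excluded from its two-genome UMI totals.

    Thresholds are the 10th percentile of the dominant-species UMI counts;
    a cell is human iff human_umi > t_human, mouse_umi < t_mouse and
    human_umi > mouse_umi.
    """
    human_umi = np.asarray(human_umi, dtype=float)
    mouse_umi = np.asarray(mouse_umi, dtype=float)
    if human_umi.shape != mouse_umi.shape:
        raise ValueError("human_umi and mouse_umi must have the same length")

    human_major = human_umi > mouse_umi
    mouse_major = mouse_umi > human_umi
    if human_major.any():
        t_human = float(np.percentile(human_umi[human_major], 10))
    else:
        warnings.warn("no human-majority cells; human threshold set to 0", stacklevel=2)
        t_human = 0.0
    if mouse_major.any():
        t_mouse = float(np.percentile(mouse_umi[mouse_major], 10))
    else:
        warnings.warn("no mouse-majority cells; mouse threshold set to +inf", stacklevel=2)
        t_mouse = np.inf

    keep = (human_umi > t_human) & (mouse_umi < t_mouse) & human_major
    labels = np.where(keep, "human", "excluded")
    return labels, SpeciesThresholds(t_human=t_human, t_mouse=t_mouse)


def density_gates(values: np.ndarray, grid_size: int = 512) -> tuple[float, float]:
    """Low/high QC gates from local minima of a KDE of log10(values + 1).

    The density (Silverman bandwidth) is evaluated on a uniform grid; the low
    gate is the left-most local minimum below the global mode, the high gate
    the right-most local minimum above it. A side with no minimum passes
    through to the data extreme.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 100:
        raise ValueError("density_gates needs at least 100 cells")
    lo_ext, hi_ext = float(values.min()), float(values.max())
    logv = np.log10(values + 1.0)
    if np.ptp(logv) == 0:
        warnings.warn("constant values; QC gates pass through", stacklevel=2)
        return lo_ext, hi_ext

    kde = gaussian_kde(logv, bw_method="silverman")
    grid = np.linspace(logv.min(), logv.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    minima = interior[(dens[interior] < dens[interior - 1]) & (dens[interior] <= dens[interior + 1])]
    mode = int(np.argmax(dens))

    left = minima[minima < mode]
    right = minima[minima > mode]
    low = float(10 ** grid[left[0]] - 1.0) if len(left) else lo_ext
    high = float(10 ** grid[right[-1]] - 1.0) if len(right) else hi_ext
    return low, high


def consensus_doublets(d: DoubletInputs) -> set[str]:
    """Barcodes removed by the dual-method consensus rule.

    Intersection of both call sets; if larger than n_expected, keep only the
    n_expected highest primary scores (ties broken by barcode order).
    """
    barcodes = np.asarray(d.barcodes, dtype=object)
    inter = d.calls_primary & d.calls_secondary
    idx = np.flatnonzero(inter)
    if len(idx) <= d.n_expected:
        return set(barcodes[idx])
    order = sorted(idx, key=lambda i: (-d.scores_primary[i], str(barcodes[i])))
    return set(barcodes[order[: d.n_expected]])


def mito_mask(var_names: pd.Index, prefix: str = "MT-") -> np.ndarray:
    """Boolean mask of mitochondrial features by symbol prefix.

    Also recognises the prefix after a genome tag (e.g. ``GRCh38_MT-ND1``).
    """
    names = var_names.astype(str)
    return np.asarray(
        names.str.startswith(prefix) | names.str.contains(f"_{prefix}", regex=False)
    )


def apply_qc(
    m: ad.AnnData,
    gates: QcGates,
    mito_genes: np.ndarray | list[str] | None = None,
    min_cells_per_gene: int = 5,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells by UMI/read gates and the strict <5% mito rule, then genes.

    Cells are retained when their UMI total (obs ``n_umi`` or computed) lies
    inside [umi_low, umi_high], read totals (obs ``n_reads`` if present)
    inside the read gates, and mito fraction strictly below ``mito_max``.
    Genes detected in fewer than ``min_cells_per_gene`` retained cells are
    dropped. Returns the filtered matrix and a per-cell pass/fail log.
    """
    x = m.X
    n_umi = (
        m.obs["n_umi"].to_numpy(dtype=float)
        if "n_umi" in m.obs
        else np.asarray(x.sum(axis=1)).ravel().astype(float)
    )
    if "mito_frac" in m.obs:
        mito_frac = m.obs["mito_frac"].to_numpy(dtype=float)
    else:
        if mito_genes is None:
            mito = mito_mask(m.var_names)
        else:
            mito = np.asarray(m.var_names.isin(list(mito_genes)))
        mito_counts = (
            np.asarray(x[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(m.n_obs)
        )
        mito_frac = np.divide(mito_counts, np.maximum(n_umi, 1.0))

    pass_umi = (n_umi >= gates.umi_low) & (n_umi <= gates.umi_high)
    if "n_reads" in m.obs:
        reads = m.obs["n_reads"].to_numpy(dtype=float)
        pass_reads = (reads >= gates.reads_low) & (reads <= gates.reads_high)
    else:
        pass_reads = np.ones(m.n_obs, dtype=bool)
    pass_mito = mito_frac < gates.mito_max

    log = pd.DataFrame(
        {
            "n_umi": n_umi,
            "mito_frac": mito_frac,
            "pass_umi": pass_umi,
            "pass_reads": pass_reads,
            "pass_mito": pass_mito,
            "pass": pass_umi & pass_reads & pass_mito,
        },
        index=m.obs_names,
    )
    keep = log["pass"].to_numpy()
    if not keep.any():
        raise ValueError(
            "all cells fail QC "
            f"(umi pass {int(pass_umi.sum())}, reads pass {int(pass_reads.sum())}, "
            f"mito pass {int(pass_mito.sum())} of {m.n_obs})"
        )
    filtered = m[keep].copy()
    detected = np.asarray((filtered.X > 0).sum(axis=0)).ravel()
    filtered = filtered[:, detected >= min_cells_per_gene].copy()
    # freeze the totals used for gating so re-filtering is a no-op
    filtered.obs["n_umi"] = n_umi[keep]
    filtered.obs["mito_frac"] = mito_frac[keep]
    return filtered, log
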