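"""Meta-cluster marker derivation: per-sample DE, Fisher combination, criteria.

Within each sample the cells of one meta cluster form a subcluster; each
subcluster is tested one-vs-rest per gene with a Wilcoxon rank-sum on the
log-normalised layer (no thresholding at this stage). Per-gene p-values are
combined across samples with Fisher's method (chi^2 = -2 sum ln p, df = 2k),
adjusted per meta cluster by Benjamini-Hochberg, and a gene becomes a marker
when FDR < 0.01 and log2FC > log2(1.25) in at least two samples. Heat-shock
(HSP*), mitochondrial (MT-*) and RPL* genes are excluded before aggregation;
the top 100 markers by combined p feed downstream analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "subcluster_de",
    "fisher_combine",
    "call_markers",
    "DEFAULT_EXCLUDED_PREFIXES",
]

DEFAULT_EXCLUDED_PREFIXES: tuple[str, ...] = ("HSP", "MT-", "RPL")

FDR_MAX = 0.01
FC_MIN_LOG2 = np.log2(1.25)
MIN_FC_SAMPLES = 2
TOP_N = 100


def _tie_terms(expr: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per gene (column)."""
    out = np.zeros(expr.shape[1])
    for j in range(expr.shape[1]):
        _, counts = np.unique(expr[:, j], return_counts=True)
        out[j] = np.sum(counts ** 3 - counts)
    return out


def _rank_sum_one_vs_rest(
    ranks: np.ndarray, tie_term: np.ndarray, in_group: np.ndarray
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (normal approx, tie-corrected).

    ``ranks`` are mid-ranks over all cells; the ranking and the tie terms are
    group-independent, so callers compute them once per sample.
    """
    n = ranks.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu - np.sign(u - mu) * 0.5) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[sigma2 <= 0] = 1.0  # constant gene
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _log2fc(expr_log: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """log2 fold change of de-logged means with a +1 pseudocount."""
    mean_in = np.expm1(expr_log[in_group]).mean(axis=0)
    mean_out = np.expm1(expr_log[~in_group]).mean(axis=0)
    return np.log2((mean_in + 1.0) / (mean_out + 1.0))


def subcluster_de(
    lognorm: pd.DataFrame,
    mc_labels: pd.Series,
    genes: list[str] | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest DE for every subcluster of one sample (one phase).

    ``lognorm`` is cells x genes log-normalised expression for a single
    sample; ``mc_labels`` maps its cells to meta clusters. Returns a long
    table (mc, gene, p, log2fc). Subclusters with fewer than ``min_cells``
    cells are skipped.
    """
    if genes is not None:
        genes = [g for g in genes if g in lognorm.columns]
        lognorm = lognorm[genes]
    mc_labels = mc_labels.loc[lognorm.index]
    groups = sorted(mc_labels.unique())
    if len(groups) < 2:
        raise ValueError("subcluster_de needs >= 2 subclusters in the sample")

    expr = lognorm.to_numpy(dtype=float)
    ranks = stats.rankdata(expr, axis=0)
    tie_term = _tie_terms(expr)
    out = []
    for mc in groups:
        in_group = (mc_labels == mc).to_numpy()
        if in_group.sum() < min_cells:
            warnings.warn(f"subcluster {mc}: fewer than {min_cells} cells; skipped",
                          stacklevel=2)
            continue
        p = _rank_sum_one_vs_rest(ranks, tie_term, in_group)
        lfc = _log2fc(expr, in_group)
        out.append(pd.DataFrame({
            "mc": mc,
            "gene": lognorm.columns,
            "p": p,
            "log2fc": lfc,
        }))
    return pd.concat(out, ignore_index=True)


def fisher_combine(p: np.ndarray | list[float]) -> tuple[float, int, float]:
    """Fisher's combined probability: chi2 = -2 sum ln p on 2k df."""
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise ValueError("fisher_combine needs at least one p-value")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float",
                      stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def call_markers(
    de_by_sample: dict[str, pd.DataFrame],
    excluded_prefixes: tuple[str, ...] = DEFAULT_EXCLUDED_PREFIXES,
    fdr_max: float = FDR_MAX,
    fc_min_log2: float = FC_MIN_LOG2,
    min_fc_samples: int = MIN_FC_SAMPLES,
    top_n: int = TOP_N,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Aggregate per-sample DE into the meta-cluster marker table.

    ``de_by_sample`` maps sample_id -> the table from :func:`subcluster_de`.
    Genes matching an excluded symbol prefix are dropped before aggregation.
    Returns the full marker table and the top-``top_n`` marker list per MC.
    """
    long = pd.concat(
        [df.assign(sample_id=s) for s, df in de_by_sample.items()], ignore_index=True
    )
    bad = long["gene"].str.startswith(excluded_prefixes)
    long = long[~bad]

    rows = []
    for mc, sub in long.groupby("mc"):
        per_gene = sub.groupby("gene")
        for gene, tab in per_gene:
            chi2, df, comb = fisher_combine(tab["p"].to_numpy())
            rows.append({
                "mc": mc,
                "gene": gene,
                "n_samples": len(tab),
                "chi2": chi2,
                "combined_p": comb,
                "n_samples_fc_pass": int((tab["log2fc"] > fc_min_log2).sum()),
                "max_log2fc": float(tab["log2fc"].max()),
            })
    table = pd.DataFrame(rows)

    parts = []
    for mc, sub in table.groupby("mc"):
        sub = sub.copy()
        sub["fdr"] = multipletests(sub["combined_p"], method="fdr_bh")[1]
        sub["is_marker"] = (sub["fdr"] < fdr_max) & (sub["n_samples_fc_pass"] >= min_fc_samples)
        sub = sub.sort_values(["combined_p", "gene"], kind="stable")
        sub["rank"] = np.arange(1, len(sub) + 1)
        if sub["is_marker"].sum() == 0 and (sub["n_samples"] == 1).all():
            warnings.warn(
                f"{mc}: present in a single sample; the 2-sample FC criterion "
                "cannot hold, marker set empty",
                stacklevel=2,
            )
        parts.append(sub)
    table = pd.concat(parts, ignore_index=True)

    top = {
        mc: list(sub[sub["is_marker"]].nsmallest(top_n, "rank")["gene"])
        for mc, sub in table.groupby("mc")
    }
    return table, top
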