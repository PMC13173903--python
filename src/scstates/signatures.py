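"""Gene-set similarity, enrichment, per-cell scoring and signature recipes.

The per-cell scorer is a signed rank-KS statistic with the same directional
semantics as single-sample gene-set variation scores: positive when the
set's genes sit unusually high in a cell's expression ranking. Pseudo-bulk
signature recipes cover the mean of log-normalised expression (RTS / PS /
CIN70 style), the negated sum of scaled expression (recombination
proficiency), and a first-principal-component score with its sign anchored
to the set mean (p53-style).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "overlap_coefficient",
    "hypergeom_enrich",
    "score_gene_set",
    "assign_states",
    "positive_fraction",
    "pseudobulk_signature",
    "score_pseudobulk",
    "metastatic_coexpression",
]

SET_SIZE_MIN = 3
SET_SIZE_MAX = 500
MIN_OVERLAP = 3
ENRICH_FDR_MAX = 0.05


def overlap_coefficient(a: set[str] | list[str], b: set[str] | list[str]) -> float:
    """|A n B| / min(|A|, |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap_coefficient requires two non-empty sets")
    return len(a & b) / min(len(a), len(b))


def hypergeom_enrich(
    markers: list[str],
    sets: dict[str, list[str]],
    universe_size: int,
    universe: set[str] | None = None,
    set_size_min: int = SET_SIZE_MIN,
    set_size_max: int = SET_SIZE_MAX,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of markers against gene sets.

    p = P(X >= k | n, N, K); sets are restricted to ``set_size_min`` to
    ``set_size_max`` genes (after intersection with the universe when one is
    given). Significance needs overlap >= 3 and BH-FDR < 0.05.
    """
    markers_set = set(markers)
    n = len(markers_set)
    rows = []
    for name, genes in sets.items():
        gs = set(genes) & universe if universe is not None else set(genes)
        big_k = len(gs)
        if not set_size_min <= big_k <= set_size_max:
            continue
        if big_k > universe_size:
            raise ValueError(f"set {name!r} larger than the universe")
        k = len(markers_set & gs)
        p = float(stats.hypergeom.sf(k - 1, universe_size, big_k, n))
        rows.append({"set": name, "k": k, "K": big_k, "n": n,
                     "N": universe_size, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = (df["k"] >= MIN_OVERLAP) & (df["fdr"] < ENRICH_FDR_MAX)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def _rank_ks_scores(expr: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    """Signed KS-like enrichment of set genes in each cell's ranking.

    Genes are ordered by decreasing expression (ties by column order); the
    running sum steps +1/K inside the set and -1/(G-K) outside. The score is
    max + min of the running deviation, in [-1, 1].
    """
    n_cells, n_genes = expr.shape
    k = int(in_set.sum())
    order = np.argsort(-expr, axis=1, kind="stable")
    hit = in_set[order]  # cells x genes walk
    step = np.where(hit, 1.0 / k, -1.0 / (n_genes - k))
    walk = np.cumsum(step, axis=1)
    return walk.max(axis=1) + np.minimum(walk.min(axis=1), 0.0)


def score_gene_set(
    expr: pd.DataFrame, gene_set: list[str], method: str = "rank-ks"
) -> pd.Series:
    """Per-cell score of a gene set on a cells x genes expression frame.

    ``rank-ks`` (default): signed rank enrichment in [-1, 1].
    ``mean-z``: mean over set genes of per-gene z-scores across cells.
    """
    in_set = np.asarray(expr.columns.isin(set(gene_set)))
    if in_set.sum() < 2:
        raise ValueError("fewer than 2 set genes present in the expression matrix")
    x = expr.to_numpy(dtype=float)
    if method == "rank-ks":
        vals = _rank_ks_scores(x, in_set)
    elif method == "mean-z":
        sd = x.std(axis=0)
        z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        vals = z[:, in_set].mean(axis=1)
    else:
        raise ValueError(f"unknown scoring method: {method}")
    return pd.Series(vals, index=expr.index, name="score")


def assign_states(scores: pd.DataFrame) -> pd.Series:
    """Assign each cell to the signature with the highest positive score.

    All scores <= 0 -> "unassigned". Ties go to the earliest column.
    """
    if scores.shape[1] < 1:
        raise ValueError("assign_states needs at least one signature column")
    vals = scores.to_numpy(dtype=float)
    best = vals.argmax(axis=1)
    assigned = scores.columns.to_numpy()[best].astype(object)
    assigned[vals.max(axis=1) <= 0] = "unassigned"
    return pd.Series(assigned, index=scores.index, name="state")


def positive_fraction(
    scores: pd.Series,
    groups: pd.Series,
    units: pd.Series | None = None,
    paired: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Fraction of score > 0 per group (and unit), with a two-group test.

    With ``units`` the fraction is computed per (group, unit) and the test
    compares per-unit fractions between the two groups: a paired t-test when
    ``paired`` (units must match across groups) else a Wilcoxon rank-sum.
    Without units, the test runs on the raw scores split by group.
    """
    levels = [g for g in pd.unique(groups) if (groups == g).sum() > 0]
    if len(levels) < 2:
        raise ValueError("positive_fraction needs >= 2 non-empty groups")
    if len(levels) > 2:
        raise ValueError("positive_fraction supports exactly 2 groups")
    g1, g2 = levels

    if units is not None:
        frac = (
            pd.DataFrame({"pos": scores > 0, "group": groups, "unit": units})
            .groupby(["group", "unit"], observed=True)["pos"]
            .mean()
            .rename("fraction")
            .reset_index()
        )
        a = frac[frac["group"] == g1].set_index("unit")["fraction"]
        b = frac[frac["group"] == g2].set_index("unit")["fraction"]
        if paired:
            common = a.index.intersection(b.index)
            d = a.loc[common] - b.loc[common]
            p = 1.0 if np.allclose(d, 0) else float(stats.ttest_rel(a.loc[common], b.loc[common]).pvalue)
        else:
            p = float(stats.ranksums(a, b).pvalue)
        return frac, p

    frac = (
        pd.DataFrame({"pos": scores > 0, "group": groups})
        .groupby("group", observed=True)["pos"]
        .mean()
        .rename("fraction")
        .reset_index()
    )
    x, y = scores[groups == g1], scores[groups == g2]
    if paired:
        d = x.to_numpy() - y.to_numpy()
        p = 1.0 if np.allclose(d, 0) else float(stats.ttest_rel(x, y).pvalue)
    else:
        p = float(stats.ranksums(x, y).pvalue)
    return frac, p


def score_pseudobulk(pb: pd.DataFrame, recipe: str) -> pd.Series:
    """Apply a signature recipe to a pseudo-bulk (group x set-gene) frame.

    mean / mean-lognorm: row mean. scaled-negsum: -1 x row sum (inputs must
    already be scaled). pc1: first principal component, sign anchored to a
    positive correlation with the row mean.
    """
    if recipe in {"mean", "mean-lognorm"}:
        return pb.mean(axis=1)
    if recipe == "scaled-negsum":
        return -pb.sum(axis=1)
    if recipe == "pc1":
        x = pb.to_numpy(dtype=float)
        xc = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        pc1 = xc @ vt[0]
        anchor = pb.mean(axis=1).to_numpy()
        if np.std(anchor) > 0 and np.corrcoef(pc1, anchor)[0, 1] < 0:
            pc1 = -pc1
        return pd.Series(pc1, index=pb.index)
    raise ValueError(f"unknown recipe: {recipe}")


def pseudobulk_signature(
    lognorm: pd.DataFrame,
    genes: list[str],
    recipe: str,
    groups: pd.Series,
) -> pd.Series:
    """Per-group signature score via pseudo-bulk mean expression.

    Pseudo-bulk is the per-gene mean of log-normalised expression over each
    group's cells; for ``scaled-negsum`` genes are z-scaled across cells
    before averaging (and every signature gene must be present).
    """
    present = [g for g in genes if g in lognorm.columns]
    if recipe == "scaled-negsum":
        missing = sorted(set(genes) - set(present))
        if missing:
            raise ValueError(f"scaled-negsum signature genes missing: {missing}")
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    x = lognorm[present]
    if recipe == "scaled-negsum":
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / sd.where(sd > 0, 1.0)
    pb = x.groupby(groups.loc[x.index], observed=True).mean()
    return score_pseudobulk(pb, recipe)


def metastatic_coexpression(x: pd.Series, y: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Per-cell co-expression r_i = x_i y_i / sqrt(x_i^2 + y_i^2), then [0,1].

    Returns (raw, min-max scaled). Cells with x = y = 0 get raw 0 with a
    warning.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    denom = np.sqrt(xv ** 2 + yv ** 2)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with x = y = 0 set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(zero, 0.0, xv * yv / np.where(zero, 1.0, denom))
    lo, hi = raw.min(), raw.max()
    scaled = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return (
        pd.Series(raw, index=x.index, name="raw"),
        pd.Series(scaled, index=x.index, name="scaled"),
    )
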