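"""AUCell-style regulon activity and meta-cluster-specific TF calling.

Per-cell activity is the normalised area under the recovery curve of a
regulon's genes within the top fraction of that cell's expression ranking
(ties broken by a seeded random permutation, so the score depends only on
ranks). A TF is specific to a meta cluster when it passes the per-sample
rank-sum and mean-difference criteria in at least one sample, shows non-zero
activity in at least two samples, has a higher median activity inside the target MC, and
qualifies for exactly one MC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import overlap_coefficient

__all__ = [
    "aucell_score",
    "mc_specific_tfs",
    "oc_vs_markers",
]

P_MAX = 0.05
MEAN_DIFF_MIN = 0.1
MIN_DETECTED_SAMPLES = 2


def aucell_score(
    expr: pd.DataFrame,
    regulon: list[str],
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Recovery-curve AUC of regulon genes in each cell's top-ranked genes.

    For each cell, genes are ranked by decreasing expression (ties
    randomised with ``seed``); within the top ``top_frac`` of ranks the
    cumulative count of regulon genes is integrated and normalised by the
    best achievable curve, giving activities in [0, 1].
    """
    if not 0.0 < top_frac <= 0.5:
        raise ValueError("top_frac must lie in (0, 0.5]")
    genes = expr.columns
    in_reg = np.asarray(genes.isin(set(regulon)))
    if in_reg.sum() < 2:
        raise ValueError("regulon must intersect the gene universe in >= 2 genes")

    n_genes = len(genes)
    window = max(int(np.ceil(top_frac * n_genes)), 1)
    k = int(in_reg.sum())
    max_auc = np.minimum(np.arange(1, window + 1), k).sum()

    rng = np.random.default_rng(seed)
    jitter = rng.permutation(n_genes)  # deterministic tie order
    x = expr.to_numpy(dtype=float)
    order = np.lexsort((jitter[None, :].repeat(x.shape[0], axis=0), -x), axis=1)
    hits = in_reg[order[:, :window]]
    recovered = np.cumsum(hits, axis=1)
    auc = recovered.sum(axis=1) / max_auc
    return pd.Series(auc, index=expr.index, name="activity")


def mc_specific_tfs(
    activity: pd.DataFrame,
    mc_labels: pd.Series,
    samples: pd.Series,
    p_max: float = P_MAX,
    mean_diff_min: float = MEAN_DIFF_MIN,
    min_detected: int = MIN_DETECTED_SAMPLES,
) -> pd.DataFrame:
    """Call TFs specific to exactly one meta cluster.

    ``activity`` is cells x TF; ``mc_labels`` and ``samples`` align on the
    same cells. Per sample, per TF, per MC: Wilcoxon rank-sum target vs rest
    with the mean-difference criterion. A TF is a candidate for an MC when
    it passes in >= 1 sample, is detected (non-constant activity) in >=
    ``min_detected`` samples, and has a higher pooled median inside the MC;
    it is *specific* when a candidate for exactly one MC.
    """
    cells = activity.index
    mc_labels = mc_labels.loc[cells]
    samples = samples.loc[cells]
    mcs = sorted(mc_labels.unique())
    if len(mcs) < 2:
        raise ValueError("mc_specific_tfs needs >= 2 meta clusters")

    detected: dict[str, int] = {}
    for tf in activity.columns:
        n_det = 0
        for s in samples.unique():
            vals = activity.loc[samples == s, tf]
            if len(vals) and vals.max() > 0:
                n_det += 1
        detected[tf] = n_det

    rows = []
    for tf in activity.columns:
        if detected[tf] == 0:
            continue
        act = activity[tf]
        for mc in mcs:
            in_mc = (mc_labels == mc).to_numpy()
            n_pass = 0
            per_sample_p = {}
            for s in samples.unique():
                sel = (samples == s).to_numpy()
                a = act[sel & in_mc]
                b = act[sel & ~in_mc]
                if len(a) < 2 or len(b) < 2:
                    continue
                p = float(stats.ranksums(a, b).pvalue)
                diff = float(a.mean() - b.mean())
                per_sample_p[s] = p
                if p < p_max and diff > mean_diff_min:
                    n_pass += 1
            med_in = float(act[in_mc].median()) if in_mc.any() else np.nan
            med_out = float(act[~in_mc].median()) if (~in_mc).any() else np.nan
            rows.append(
                {
                    "tf": tf,
                    "mc": mc,
                    "n_samples_pass": n_pass,
                    "n_samples_detected": detected[tf],
                    "median_in": med_in,
                    "median_out": med_out,
                    "candidate": (
                        n_pass >= 1
                        and detected[tf] >= min_detected
                        and med_in > med_out
                    ),
                }
            )
    res = pd.DataFrame(rows)
    n_candidate = res.groupby("tf")["candidate"].sum()
    res["specific"] = res.apply(
        lambda r: bool(r["candidate"]) and n_candidate[r["tf"]] == 1, axis=1
    )
    return res


def oc_vs_markers(
    regulons: dict[str, list[str]],
    mc_markers: dict[str, list[str]],
    p_max: float = P_MAX,
) -> pd.DataFrame:
    """Overlap coefficients of regulons against MC top-marker lists, with a t-test.

    For each (TF, target MC) the target OC is compared against the TF's OC
    values with the other MCs by a one-sample t-test (popmean = target OC);
    the pair is flagged when p < ``p_max`` and the target OC exceeds the
    others' mean. Fewer than 2 other-MC values leaves p undefined (NaN).
    This literal test on a handful of bounded values is statistically
    unusual; treat the flag as descriptive.
    """
    mcs = sorted(mc_markers)
    rows = []
    for tf, genes in regulons.items():
        ocs = {mc: overlap_coefficient(genes, mc_markers[mc]) if mc_markers[mc] else 0.0
               for mc in mcs}
        for mc in mcs:
            others = np.array([ocs[m] for m in mcs if m != mc], dtype=float)
            if len(others) < 2 or np.allclose(others.std(ddof=1), 0):
                p = np.nan
            else:
                p = float(stats.ttest_1samp(others, popmean=ocs[mc]).pvalue)
            rows.append(
                {
                    "tf": tf,
                    "mc": mc,
                    "oc": ocs[mc],
                    "oc_others_mean": float(others.mean()) if len(others) else np.nan,
                    "p": p,
                    "flag": bool(
                        np.isfinite(p) and p < p_max and ocs[mc] > others.mean()
                    ),
                }
            )
    return pd.DataFrame(rows)
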