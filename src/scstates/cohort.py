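"""Clinical validation of state signatures: survival and response statistics.

Median split (ties to "low"), proportional-hazards association censored at a
10-year horizon (delegated to lifelines), one-sided Wilcoxon rank-sum per
arm, and the sample-size-weighted sum-of-z combination across arms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "median_split",
    "survival_assoc",
    "response_assoc",
    "combine_weighted_z",
]


def median_split(scores: pd.Series) -> pd.Series:
    """"low" iff score <= median, else "high"."""
    if len(scores) < 4:
        raise ValueError("median_split needs at least 4 patients")
    med = float(np.median(scores))
    if np.all(scores == scores.iloc[0]):
        warnings.warn("all scores equal; every patient labelled low", stacklevel=2)
    return pd.Series(
        np.where(scores <= med, "low", "high"), index=scores.index, name="group"
    )


def survival_assoc(
    groups: pd.Series,
    time: pd.Series,
    event: pd.Series,
    horizon_years: float = 10.0,
) -> dict:
    """Cox PH of high vs low groups, censored at ``horizon_years``.

    Returns hazard ratio, 95% CI and Wald p. ``groups`` must hold
    "low"/"high" labels; observations past the horizon are administratively
    censored there.
    """
    df = pd.DataFrame({
        "time": time.astype(float),
        "event": event.astype(int),
        "high": (groups == "high").astype(int),
    })
    if df["high"].nunique() < 2:
        raise ValueError("both groups must be non-empty")
    over = df["time"] > horizon_years
    df.loc[over, "event"] = 0
    df.loc[over, "time"] = horizon_years
    if df["event"].sum() == 0:
        warnings.warn("no events within the horizon; HR undefined", stacklevel=2)
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "n_events": 0}

    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["high"]
    return {
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "p": float(s["p"]),
        "n_events": int(df["event"].sum()),
    }


def response_assoc(
    scores: pd.Series,
    labels: pd.Series,
    direction: str = "RD-high",
    exact_below: int = 50,
) -> float:
    """One-sided Wilcoxon rank-sum p of signature scores between RD and pCR.

    direction="RD-high" tests scores(RD) > scores(pCR); "pCR-high" the
    reverse. The exact distribution is used for small tie-free arms, the
    tie-corrected normal approximation otherwise.
    """
    if direction not in {"RD-high", "pCR-high"}:
        raise ValueError("direction must be 'RD-high' or 'pCR-high'")
    rd = scores[labels == "RD"]
    pcr = scores[labels == "pCR"]
    if len(rd) == 0 or len(pcr) == 0:
        raise ValueError("both response labels must be present in the arm")
    x, y = (rd, pcr) if direction == "RD-high" else (pcr, rd)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) < exact_below and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def combine_weighted_z(p: np.ndarray | list[float], weights: np.ndarray | list[float]) -> float:
    """Sum-of-z combination: Z = sum(w z) / sqrt(sum w^2), p = 1 - Phi(Z)."""
    p = np.asarray(p, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape or p.size == 0:
        raise ValueError("p and weights must be equal-length, non-empty")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    eps = np.finfo(float).tiny
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values clamped away from {0, 1}", stacklevel=2)
        p = np.clip(p, eps, 1 - 1e-16)
    z = stats.norm.isf(p)
    big_z = float(np.dot(w, z) / np.sqrt(np.dot(w, w)))
    return float(stats.norm.sf(big_z))
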