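"""Synthetic data with planted ground truth for every pipeline stage.

Generates (i) barnyard-style human/mouse UMI mixtures with doublets, (ii)
multi-sample cohorts of cell x gene counts carrying planted transcriptional
states, batch shifts, cell-cycle programmes and QC artefacts, and (iii) bulk
clinical cohorts whose response or survival depends on a planted gene
signature.

Counts follow a gamma-Poisson (negative binomial) model: gene baseline
weights are log-normal, per-sample batch factors multiply gene means, and
state / cell-cycle programmes multiply their member genes. The truth labels
needed to score every downstream stage are returned alongside the matrices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._gene_lists import G2M_PHASE_GENES, S_PHASE_GENES

__all__ = [
    "StateSpec",
    "CohortTruth",
    "build_gene_universe",
    "nb_counts",
    "generate_barnyard",
    "generate_cohort",
    "generate_clinical",
    "default_states",
]


@dataclass(frozen=True)
class StateSpec:
    """A planted transcriptional state: its markers, effect size and prevalence."""

    state_id: str
    marker_genes: tuple[str, ...]
    log2_effect: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.log2_effect < 0:
            raise ValueError("log2_effect must be non-negative")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass
class CohortTruth:
    """Ground-truth labels for a generated dataset.

    ``cells`` has one row per emitted barcode (sample_id, state_id, phase,
    species, is_low_quality plus synthetic doublet scores/calls); ``genes``
    maps every feature to its class (``marker:<state>``, housekeeping, mito,
    rpl, hsp, cc_s, cc_g2m, mouse). ``params`` records the generator inputs.
    """

    cells: pd.DataFrame
    genes: pd.Series
    params: dict = field(default_factory=dict)


def nb_counts(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial draws with mean ``mu`` and dispersion ``theta``.

    var = mu + mu^2 / theta, sampled as a gamma-Poisson mixture.
    """
    mu = np.asarray(mu, dtype=float)
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    return rng.poisson(lam)


def build_gene_universe(n_genes: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Gene symbols and classes for the synthetic human feature space.

    Includes 20 ``MT-`` mitochondrial, 40 ``RPL`` ribosomal, 20 ``HSP``
    heat-shock, the 43 S-phase and 54 G2M-phase consensus genes, with the
    remainder named ``GENE%04d`` (class housekeeping). Baseline log-weights
    are drawn N(0, 1) from ``seed``.
    """
    special = (
        [(f"MT-SYN{i + 1}", "mito") for i in range(20)]
        + [(f"RPL{i + 1}", "rpl") for i in range(40)]
        + [(f"HSPX{i + 1}", "hsp") for i in range(20)]
        + [(g, "cc_s") for g in S_PHASE_GENES]
        + [(g, "cc_g2m") for g in G2M_PHASE_GENES]
    )
    if n_genes < len(special) + 100:
        raise ValueError(f"n_genes must be at least {len(special) + 100}")
    n_hk = n_genes - len(special)
    genes = special + [(f"GENE{i + 1:04d}", "housekeeping") for i in range(n_hk)]
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(genes, columns=["symbol", "gene_class"]).set_index("symbol")
    df["log_weight"] = rng.normal(0.0, 1.0, size=len(df))
    return df


def default_states(
    universe: pd.DataFrame,
    n_states: int = 4,
    markers_per_state: int = 60,
    log2_effect: float = 2.0,
    seed: int = 0,
) -> list[StateSpec]:
    """Equal-prevalence states with disjoint marker programmes.

    Markers are drawn from the lower half of the housekeeping baseline-weight
    distribution so the planted fold change moves them far in rank space.
    """
    rng = np.random.default_rng(seed)
    hk = universe[universe["gene_class"] == "housekeeping"]
    pool = hk[hk["log_weight"] <= hk["log_weight"].median()].index.to_numpy()
    need = n_states * markers_per_state
    if len(pool) < need:
        pool = hk.index.to_numpy()
    chosen = rng.choice(pool, size=need, replace=False)
    prev = 1.0 / n_states
    return [
        StateSpec(
            state_id=f"S{i}",
            marker_genes=tuple(sorted(chosen[i * markers_per_state:(i + 1) * markers_per_state])),
            log2_effect=log2_effect,
            prevalence=prev,
        )
        for i in range(n_states)
    ]


def _check_disjoint(states: list[StateSpec]) -> None:
    seen: set[str] = set()
    for s in states:
        overlap = seen.intersection(s.marker_genes)
        if overlap:
            raise ValueError(f"marker sets must be pairwise disjoint; shared: {sorted(overlap)[:5]}")
        seen.update(s.marker_genes)


def _doublet_annotation(
    human: np.ndarray, mouse: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Synthetic doublet scores/calls derived from per-cell species purity."""
    total = np.maximum(human + mouse, 1)
    purity = np.maximum(human, mouse) / total
    score_a = np.clip(1.0 - purity + rng.normal(0.0, 0.02, size=len(total)), 0.0, 1.0)
    score_b = np.clip(1.0 - purity + rng.normal(0.0, 0.02, size=len(total)), 0.0, 1.0)
    return pd.DataFrame(
        {
            "doublet_score_primary": score_a,
            "doublet_call_primary": score_a > 0.30,
            "doublet_call_secondary": score_b > 0.30,
        }
    )


def generate_barnyard(
    n_human: int,
    n_mouse: int,
    doublet_rate: float,
    seed: int,
    n_genes_per_species: int = 300,
    mean_umi: float = 4000.0,
    theta: float = 10.0,
) -> tuple[ad.AnnData, CohortTruth]:
    """Human/mouse UMI mixture with an optional planted doublet fraction.

    Singlets draw >= 95% of their UMIs from their own species' feature block;
    doublets are literal sums of one fresh human and one fresh mouse draw and
    are appended after the singlets. Feature ids carry ``GRCh38_``/``mm10_``
    prefixes so species can be recovered from the feature table alone.
    """
    if n_human <= 0 or n_mouse <= 0:
        raise ValueError("n_human and n_mouse must be positive")
    if not 0.0 <= doublet_rate <= 0.3:
        raise ValueError("doublet_rate must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)

    n_doublets = int(round(doublet_rate * (n_human + n_mouse)))
    hw = np.exp(rng.normal(0.0, 1.0, size=n_genes_per_species))
    mw = np.exp(rng.normal(0.0, 1.0, size=n_genes_per_species))
    hw /= hw.sum()
    mw /= mw.sum()

    def _draw_cells(n: int, own: np.ndarray, other: np.ndarray) -> np.ndarray:
        """Rows: cells; cols: [own block | other block]."""
        contam = rng.uniform(0.005, 0.04, size=n)
        totals = np.maximum(rng.lognormal(np.log(mean_umi), 0.3, size=n), 50).astype(int)
        out = np.zeros((n, 2 * n_genes_per_species), dtype=np.int64)
        for i in range(n):
            p = np.concatenate([(1 - contam[i]) * own, contam[i] * other])
            out[i] = rng.multinomial(totals[i], p)
        return out

    human_rows = _draw_cells(n_human + n_doublets, hw, mw)  # [human | mouse]
    mouse_rows = _draw_cells(n_mouse + n_doublets, mw, hw)  # [mouse | human]
    mouse_rows = np.concatenate(
        [mouse_rows[:, n_genes_per_species:], mouse_rows[:, :n_genes_per_species]], axis=1
    )  # reorder to [human | mouse]

    x = np.concatenate(
        [
            human_rows[:n_human],
            mouse_rows[:n_mouse],
            human_rows[n_human:] + mouse_rows[n_mouse:],
        ],
        axis=0,
    )
    barcodes = (
        [f"H{i:05d}" for i in range(n_human)]
        + [f"M{i:05d}" for i in range(n_mouse)]
        + [f"D{i:05d}" for i in range(n_doublets)]
    )
    features = [f"GRCh38_HG{i + 1:04d}" for i in range(n_genes_per_species)] + [
        f"mm10_MG{i + 1:04d}" for i in range(n_genes_per_species)
    ]
    species = np.array(["human"] * n_human + ["mouse"] * n_mouse + ["doublet"] * n_doublets)
    human_umi = x[:, :n_genes_per_species].sum(axis=1)
    mouse_umi = x[:, n_genes_per_species:].sum(axis=1)

    adata = ad.AnnData(
        X=sp.csr_matrix(x),
        obs=pd.DataFrame(
            {
                "sample_id": "barnyard",
                "human_umi": human_umi,
                "mouse_umi": mouse_umi,
            },
            index=pd.Index(barcodes, name="barcode"),
        ),
        var=pd.DataFrame(
            {"species": ["human"] * n_genes_per_species + ["mouse"] * n_genes_per_species},
            index=pd.Index(features, name="symbol"),
        ),
    )
    cells = pd.DataFrame(
        {
            "sample_id": "barnyard",
            "state_id": "none",
            "phase": "G1",
            "species": species,
            "is_low_quality": False,
            "parent_a": [""] * n_human + [""] * n_mouse + [f"H+{i}" for i in range(n_doublets)],
            "parent_b": [""] * n_human + [""] * n_mouse + [f"M+{i}" for i in range(n_doublets)],
        },
        index=adata.obs_names,
    )
    cells = pd.concat([cells, _doublet_annotation(human_umi, mouse_umi, rng).set_index(adata.obs_names)], axis=1)
    truth = CohortTruth(
        cells=cells,
        genes=pd.Series(
            ["human"] * n_genes_per_species + ["mouse"] * n_genes_per_species,
            index=features,
            name="gene_class",
        ),
        params={"n_human": n_human, "n_mouse": n_mouse, "doublet_rate": doublet_rate, "seed": seed},
    )
    return adata, truth


def generate_cohort(
    n_samples: int,
    states: list[StateSpec],
    cells_per_sample: int,
    batch_sd: float = 0.2,
    seed: int = 0,
    n_genes: int = 2000,
    theta: float = 10.0,
    mean_umi: float = 5000.0,
    sg2m_frac: float = 0.3,
    cc_log2_effect: float = 2.0,
    mito_beta: tuple[float, float] = (2.5, 100.0),
    low_quality_frac: float = 0.02,
    n_mouse_genes: int = 100,
    ambient_mouse_frac: float = 0.01,
    doublet_rate: float = 0.0,
) -> tuple[list[ad.AnnData], CohortTruth]:
    """Multi-sample cohort with planted states, batch shifts and QC artefacts.

    Every sample shares the gene universe and state programmes; each sample
    gets its own multiplicative log-normal batch factor per gene (sd
    ``batch_sd``). S/G2M cells over-express both cell-cycle gene classes by
    ``cc_log2_effect`` (log2). Mitochondrial mass fraction is Beta-distributed
    with a small tail above 5%; ``low_quality_frac`` of cells get extreme UMI
    totals. A small mouse feature block provides ambient cross-species counts
    and, when ``doublet_rate`` > 0, appended human+mouse doublets.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3 (shared-HVG rule needs three samples)")
    if cells_per_sample <= 0:
        raise ValueError("cells_per_sample must be positive")
    if not 0.0 <= doublet_rate <= 0.3:
        raise ValueError("doublet_rate must lie in [0, 0.3]")
    prev_sum = sum(s.prevalence for s in states)
    if prev_sum > 1.0 + 1e-9:
        raise ValueError(f"state prevalences sum to {prev_sum:.3f} > 1")
    _check_disjoint(states)

    rng = np.random.default_rng(seed)
    universe = build_gene_universe(n_genes=n_genes, seed=seed)
    gene_class = universe["gene_class"].copy()
    for s in states:
        missing = set(s.marker_genes) - set(universe.index)
        if missing:
            raise ValueError(f"marker genes not in universe: {sorted(missing)[:5]}")
        gene_class.loc[list(s.marker_genes)] = f"marker:{s.state_id}"

    genes = universe.index.to_numpy()
    n_h = len(genes)
    is_mito = (gene_class == "mito").to_numpy()
    is_cc = gene_class.isin(["cc_s", "cc_g2m"]).to_numpy()
    base_w = np.exp(universe["log_weight"].to_numpy())

    mouse_genes = [f"mm10_MG{i + 1:04d}" for i in range(n_mouse_genes)]
    mouse_w = np.exp(rng.normal(0.0, 1.0, size=n_mouse_genes))
    mouse_w /= mouse_w.sum()

    state_ids = np.array([s.state_id for s in states])
    prevs = np.array([s.prevalence for s in states], dtype=float)
    prevs = prevs / prevs.sum()  # leftover mass redistributed proportionally
    marker_mask = np.stack(
        [np.isin(genes, np.asarray(s.marker_genes)) for s in states], axis=0
    )
    effects = np.array([2.0 ** s.log2_effect for s in states])

    adatas: list[ad.AnnData] = []
    cell_rows: list[pd.DataFrame] = []
    for si in range(n_samples):
        sample_id = f"sample{si + 1}"
        batch = np.exp(rng.normal(0.0, batch_sd, size=n_h))
        n_cells = cells_per_sample
        n_doub = int(round(doublet_rate * n_cells))

        z = rng.choice(len(states), size=n_cells + n_doub, p=prevs)
        phase = np.where(rng.random(n_cells + n_doub) < sg2m_frac, "S/G2M", "G1")
        mito_frac = rng.beta(*mito_beta, size=n_cells + n_doub)
        totals = rng.lognormal(np.log(mean_umi), 0.3, size=n_cells + n_doub)
        low_q = rng.random(n_cells) < low_quality_frac
        lw = np.where(rng.random(n_cells) < 0.5, 8.0, 0.04)
        totals[:n_cells] = np.where(low_q, totals[:n_cells] * lw, totals[:n_cells])

        x = np.zeros((n_cells + n_doub, n_h), dtype=np.int64)
        xm = np.zeros((n_cells + n_doub, n_mouse_genes), dtype=np.int64)
        for ci in range(n_cells + n_doub):
            w = base_w * batch
            w = np.where(marker_mask[z[ci]], w * effects[z[ci]], w)
            if phase[ci] == "S/G2M":
                w = np.where(is_cc, w * 2.0 ** cc_log2_effect, w)
            w_nm = np.where(is_mito, 0.0, w)
            p = np.zeros(n_h)
            p[~is_mito] = (1.0 - mito_frac[ci]) * w_nm[~is_mito] / w_nm[~is_mito].sum()
            p[is_mito] = mito_frac[ci] * base_w[is_mito] / base_w[is_mito].sum()
            t_h = totals[ci] * (1.0 - ambient_mouse_frac)
            x[ci] = nb_counts(t_h * p, theta, rng)
            if n_mouse_genes:
                xm[ci] = rng.multinomial(
                    int(round(totals[ci] * ambient_mouse_frac)), mouse_w
                )

        # doublets: singlet row + a mouse-dominant companion draw
        species = np.array(["human"] * (n_cells + n_doub))
        if n_doub:
            for di in range(n_doub):
                t_m = rng.lognormal(np.log(mean_umi), 0.3)
                xm[n_cells + di] += rng.multinomial(int(t_m * 0.98), mouse_w)
                extra_h = rng.multinomial(int(t_m * 0.02), base_w / base_w.sum())
                x[n_cells + di] += extra_h
            species[n_cells:] = "doublet"

        barcodes = [f"{sample_id}_C{i:05d}" for i in range(n_cells)] + [
            f"{sample_id}_D{i:05d}" for i in range(n_doub)
        ]
        full = np.concatenate([x, xm], axis=1) if n_mouse_genes else x
        var = pd.DataFrame(
            {
                "species": ["human"] * n_h + ["mouse"] * n_mouse_genes,
                "feature_id": [f"GRCh38_{g}" for g in genes] + mouse_genes,
            },
            index=pd.Index(list(genes) + mouse_genes, name="symbol"),
        )
        human_umi = x.sum(axis=1)
        mouse_umi = xm.sum(axis=1) if n_mouse_genes else np.zeros(n_cells + n_doub, dtype=int)
        obs = pd.DataFrame(
            {
                "sample_id": sample_id,
                "human_umi": human_umi,
                "mouse_umi": mouse_umi,
            },
            index=pd.Index(barcodes, name="barcode"),
        )
        adatas.append(ad.AnnData(X=sp.csr_matrix(full), obs=obs, var=var))

        cells = pd.DataFrame(
            {
                "sample_id": sample_id,
                "state_id": state_ids[z],
                "phase": phase,
                "species": species,
                "is_low_quality": np.concatenate([low_q, np.zeros(n_doub, dtype=bool)]),
            },
            index=obs.index,
        )
        cells = pd.concat(
            [cells, _doublet_annotation(human_umi, mouse_umi, rng).set_index(obs.index)],
            axis=1,
        )
        cell_rows.append(cells)

    gene_truth = pd.concat(
        [gene_class, pd.Series("mouse", index=mouse_genes, name="gene_class")]
    )
    gene_truth.name = "gene_class"
    truth = CohortTruth(
        cells=pd.concat(cell_rows),
        genes=gene_truth,
        params={
            "n_samples": n_samples,
            "cells_per_sample": cells_per_sample,
            "batch_sd": batch_sd,
            "seed": seed,
            "theta": theta,
            "states": [dataclasses.asdict(s) for s in states],
        },
    )
    return adatas, truth


def generate_clinical(
    n_patients: int,
    signature: list[str],
    effect: float,
    outcome: str,
    seed: int,
    n_genes: int = 500,
    rd_fraction: float = 0.5,
    baseline_hazard: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Bulk cohort whose outcome depends on a planted signature.

    outcome="response": RD patients' signature genes are shifted upward by
    ``effect`` (in units of the per-gene noise SD); labels are RD/pCR.
    outcome="survival": patients whose planted signature score exceeds the
    cohort median get hazard multiplied by exp(effect), i.e. a planted
    high-vs-low hazard ratio of exp(effect); times are censored at ~12 years.

    Returns (expression patients x genes, labels, truth dict).
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    if not signature:
        raise ValueError("signature must contain at least one gene")
    if outcome not in {"response", "survival"}:
        raise ValueError("outcome must be 'response' or 'survival'")
    rng = np.random.default_rng(seed)

    sig = list(dict.fromkeys(signature))
    extra = [f"BGENE{i + 1:04d}" for i in range(max(0, n_genes - len(sig)))]
    genes = sig + extra
    mu = rng.normal(0.0, 1.0, size=len(genes))
    expr = mu[None, :] + rng.normal(0.0, 1.0, size=(n_patients, len(genes)))
    expr = pd.DataFrame(
        expr,
        index=pd.Index([f"P{i + 1:04d}" for i in range(n_patients)], name="patient"),
        columns=genes,
    )
    truth: dict = {"effect": effect, "signature": sig, "outcome": outcome, "seed": seed}

    if outcome == "response":
        is_rd = rng.random(n_patients) < rd_fraction
        expr.loc[is_rd, sig] += effect
        labels = pd.DataFrame(
            {"response": np.where(is_rd, "RD", "pCR")}, index=expr.index
        )
        truth["is_rd"] = pd.Series(is_rd, index=expr.index)
        return expr, labels, truth

    score = expr[sig].mean(axis=1)
    high = (score > score.median()).to_numpy()
    hazard = baseline_hazard * np.where(high, np.exp(effect), 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(4.0, 12.0, size=n_patients)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    labels = pd.DataFrame({"time": time, "event": event}, index=expr.index)
    truth["high_group"] = pd.Series(high, index=expr.index)
    truth["hazard_ratio"] = float(np.exp(effect))
    return expr, labels, truth
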