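"""Variant-retention filters and copy-number standardisation.

A variant survives when all four hold: (i) splice-site, or exonic with a
known functional consequence other than a synonymous SNV; (ii) read depth
>= 5; (iii) HIGH or MODERATE predicted impact; (iv) absent from gnomAD,
population allele frequency < 0.001, or carrying any ClinVar annotation.
Segment log2 ratios are divided by the per-sample SD (n-1 denominator);
standardised values > 3 are gains, < -3 losses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "filter_variants",
    "standardize_cna",
    "read_variant_table",
    "read_variant_vcf",
    "DEFAULT_KNOWN_CONSEQUENCES",
    "DEFAULT_VCF_INFO_MAP",
]

# annotation tools differ in INFO key naming; remap as needed
DEFAULT_VCF_INFO_MAP: dict[str, str] = {
    "gene": "GENE",
    "effect": "EFFECT",
    "read_depth": "DP",
    "impact": "IMPACT",
    "gnomad_af": "gnomAD_AF",
    "clinvar": "CLNSIG",
}

DEFAULT_KNOWN_CONSEQUENCES: tuple[str, ...] = (
    "frameshift",
    "stopgain",
    "stoploss",
    "missense",
    "splice",
    "startloss",
    "inframe_insertion",
    "inframe_deletion",
)

REQUIRED_COLUMNS = ("gene", "effect", "read_depth", "impact")

DEPTH_MIN = 5
AF_MAX = 0.001
SD_CALL_THRESHOLD = 3.0


def read_variant_table(path: str) -> pd.DataFrame:
    """Read a flat TSV of annotated variants, validating required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing required column(s): {missing}")
    return df


def read_variant_vcf(
    path: str, info_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read annotated variants from a VCF, mapping INFO keys to table columns.

    ``info_map`` maps required column names (gene, effect, read_depth,
    impact, plus optional gnomad_af, clinvar) to the INFO keys the annotator
    emitted. Missing optional keys become NaN/empty.
    """
    from cyvcf2 import VCF

    info_map = {**DEFAULT_VCF_INFO_MAP, **(info_map or {})}
    rows = []
    for v in VCF(path):
        row = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": ",".join(v.ALT),
        }
        for col, key in info_map.items():
            row[col] = v.INFO.get(key)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError(f"no variant records in {path}")
    missing = [c for c in REQUIRED_COLUMNS if df[c].isna().all()]
    if missing:
        raise ValueError(
            f"variant table missing required column(s): {missing} "
            f"(checked INFO keys {[info_map[c] for c in missing]})"
        )
    df["clinvar"] = df["clinvar"].fillna("")
    return df


def filter_variants(
    variants: pd.DataFrame,
    known_consequences: tuple[str, ...] = DEFAULT_KNOWN_CONSEQUENCES,
    depth_min: int = DEPTH_MIN,
    af_max: float = AF_MAX,
) -> pd.DataFrame:
    """Apply the four retention clauses; returns the retained rows.

    Expected columns: gene, effect (consequence class), read_depth, impact,
    and optionally gnomad_af (NaN = absent) and clinvar (empty/NaN = absent).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing required column(s): {missing}")
    eff = variants["effect"].astype(str).str.lower()

    is_splice = eff.str.contains("splice")
    is_synonymous = eff.str.contains("synonymous")
    known = eff.apply(lambda e: any(k in e for k in known_consequences))
    clause_class = is_splice | (known & ~is_synonymous)

    clause_depth = variants["read_depth"].astype(float) >= depth_min
    clause_impact = variants["impact"].astype(str).str.upper().isin(["HIGH", "MODERATE"])

    if "gnomad_af" in variants.columns:
        af = pd.to_numeric(variants["gnomad_af"], errors="coerce")
        absent = af.isna()
        rare = af < af_max
    else:
        absent = pd.Series(True, index=variants.index)
        rare = pd.Series(False, index=variants.index)
    if "clinvar" in variants.columns:
        clin = variants["clinvar"].fillna("").astype(str).str.strip() != ""
    else:
        clin = pd.Series(False, index=variants.index)
    clause_pop = absent | rare | clin

    keep = clause_class & clause_depth & clause_impact & clause_pop
    return variants[keep].copy()


def standardize_cna(segments: pd.DataFrame) -> pd.DataFrame:
    """Standardise per-sample log2 ratios and call gains/losses.

    Expected columns: sample, log2fc (chrom/start/end pass through).
    Adds ``standardized`` (log2fc / per-sample SD, n-1 denominator) and
    ``call`` in {gain, loss, neutral}. A zero-SD sample is all neutral.
    """
    if "sample" not in segments.columns or "log2fc" not in segments.columns:
        raise ValueError("segments need 'sample' and 'log2fc' columns")
    out = segments.copy()
    std = np.full(len(out), np.nan)
    sample_keys = out["sample"].to_numpy()
    log2fc = out["log2fc"].to_numpy(dtype=float)
    for s in pd.unique(sample_keys):
        pos = np.flatnonzero(sample_keys == s)  # positional: robust to dup index
        if len(pos) < 2:
            raise ValueError(f"sample {s!r}: need >= 2 segments to estimate SD")
        sd = float(np.std(log2fc[pos], ddof=1))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"sample {s!r}: zero SD; all segments neutral", stacklevel=2)
            std[pos] = 0.0
        else:
            std[pos] = log2fc[pos] / sd
    out["standardized"] = std
    out["call"] = np.select(
        [out["standardized"] > SD_CALL_THRESHOLD, out["standardized"] < -SD_CALL_THRESHOLD],
        ["gain", "loss"],
        default="neutral",
    )
    return out
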