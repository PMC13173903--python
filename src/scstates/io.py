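"""Readers and writers for the plain-text interchange formats of the pipeline.

10x-style MTX triplets (matrix.mtx + barcodes.tsv + features.tsv), GMT gene-set
collections, and TSV tables. Everything round-trips through pandas/scipy so the
on-disk artefacts stay text-only and diff-able.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_mtx_triplet",
    "read_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "load_packaged_signatures",
]


def write_mtx_triplet(adata: ad.AnnData, outdir: str | os.PathLike) -> Path:
    """Write ``adata`` as an uncompressed 10x-style triplet under ``outdir``.

    Features are written as (feature_id, gene_symbol, feature_type); barcodes
    as one barcode per line. The matrix is stored genes x cells, matching the
    CellRanger orientation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = sp.csc_matrix(adata.X).T.astype(np.int64)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), x, field="integer")
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    feat = pd.DataFrame(
        {
            "feature_id": adata.var.get("feature_id", pd.Series(adata.var_names, index=adata.var_names)),
            "symbol": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feat.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    return outdir


def read_mtx_triplet(indir: str | os.PathLike) -> ad.AnnData:
    """Read an uncompressed triplet written by :func:`write_mtx_triplet`."""
    indir = Path(indir)
    x = scipy.io.mmread(str(indir / "matrix.mtx"))
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    feat = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    adata = ad.AnnData(
        X=sp.csr_matrix(x.T),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(
            {"feature_id": feat[0].astype(str).values},
            index=pd.Index(feat[1].astype(str), name="symbol"),
        ),
    )
    adata.var_names_make_unique()
    return adata


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes...]}`` (description dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = [g for g in parts[2:] if g]
            if genes:
                sets[parts[0]] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike,
              description: str = "scstates") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def load_packaged_signatures() -> dict[str, list[str]]:
    """Gene sets shipped with the package (currently the 4-gene RPS set).

    Published signature collections are not redistributed; supply your own
    GMT files for the remaining recipes.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("scstates").joinpath("data/signatures.gmt")
    ) as p:
        return read_gmt(p)
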