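"""Dataset serialization: MTX layers with TSV sidecars, lossless round-trip.

Layout of a dataset directory::

    spliced.mtx        genes x cells integer MatrixMarket (CellRanger orientation)
    unspliced.mtx      same shape
    genes.tsv          one row per gene (gene, is_mito, is_ribo)
    cells.tsv          one row per cell (cell, condition, batch, ...)
    truth_*.tsv        ground-truth ledger (only for synthetic data)
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthdata import GroundTruth

__all__ = ["write_dataset", "read_dataset"]


def write_dataset(adata: ad.AnnData, path: Path, truth: GroundTruth | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for layer in ("spliced", "unspliced"):
        mat = sp.csc_matrix(np.asarray(adata.layers[layer]).T)  # genes x cells
        scipy.io.mmwrite(path / f"{layer}.mtx", mat, field="integer")
    var = adata.var.copy()
    var.insert(0, "gene", adata.var_names)
    var.to_csv(path / "genes.tsv", sep="\t", index=False)
    obs = adata.obs.copy()
    obs.insert(0, "cell", adata.obs_names)
    obs.to_csv(path / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_dir(path)


def read_dataset(path: Path) -> tuple[ad.AnnData, GroundTruth | None]:
    path = Path(path)
    layers = {}
    for layer in ("spliced", "unspliced"):
        mat = scipy.io.mmread(path / f"{layer}.mtx")
        layers[layer] = np.asarray(sp.csr_matrix(mat).todense()).T.astype(np.int64)
    var = pd.read_csv(path / "genes.tsv", sep="\t").set_index("gene")
    obs = pd.read_csv(path / "cells.tsv", sep="\t", dtype={"cell": str}).set_index("cell")
    adata = ad.AnnData(X=layers["spliced"], obs=obs, var=var)
    adata.layers["spliced"] = layers["spliced"]
    adata.layers["unspliced"] = layers["unspliced"]
    truth = None
    if (path / "truth_subtypes.tsv").exists():
        truth = GroundTruth.from_dir(path)
    return adata, truth
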