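"""Steady-state RNA velocity and the differentially-speeded (DS) gene statistic.

The model treats spliced abundance S and unspliced abundance U of a gene g in
cell c as linked by ``dS/dt = beta * U_g(c) - gamma_g * S_g(c)`` with
``beta = 1``: at transcriptional steady state U = gamma * S, so the residual
``v = U - gamma * S`` (the RNA velocity) is positive for genes whose
expression is about to rise.  gamma is fitted per gene by a zero-intercept
least-squares regression of pooled unspliced on pooled spliced abundance over
the cells in the extreme spliced quantiles (``fit_quantile = 0.5`` uses all
cells).

A gene is called differentially speeded between two conditions when the point
(mean velocity in the naive condition, mean velocity in the inflamed
condition) lies further than ``ds_distance_min`` from the identity line —
perpendicular distance ``d = |y - x| / sqrt(2)``.  For that single distance
threshold to be meaningful across genes of different abundance, the
per-condition mean velocities are, by default, expressed relative to the
gene's mean pooled spliced abundance within the subtype (pass
``spliced=None`` for the absolute scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "VelocityParams",
    "filter_velocity_genes",
    "pool_knn",
    "fit_gamma",
    "velocity_values",
    "ds_genes",
    "unspliced_residuals",
    "de_ds_intersect",
]


@dataclass(frozen=True)
class VelocityParams:
    k_cells: int = 5
    fit_quantile: float = 0.5
    min_max_cluster_avg_spliced: float = 5.0
    min_max_cluster_avg_unspliced: float = 1.0
    beta: float = 1.0
    ds_distance_min: float = 0.1

    def __post_init__(self) -> None:
        if self.k_cells < 0:
            raise ValueError("k_cells must be non-negative")
        if not 0 < self.fit_quantile <= 0.5:
            raise ValueError("fit_quantile must be in (0, 0.5]")
        if (
            self.min_max_cluster_avg_spliced < 0
            or self.min_max_cluster_avg_unspliced < 0
            or self.ds_distance_min < 0
        ):
            raise ValueError("thresholds must be non-negative")


def filter_velocity_genes(
    spliced: pd.DataFrame,
    unspliced: pd.DataFrame,
    cluster_labels: np.ndarray,
    params: VelocityParams = VelocityParams(),
    protein_coding: set[str] | None = None,
) -> list[str]:
    """Genes whose best cluster-mean count reaches the spliced AND unspliced
    thresholds (optionally intersected with a protein-coding gene list)."""
    labels = np.asarray(cluster_labels)
    if len(labels) != len(spliced):
        raise ValueError("cluster labels must cover all cells")
    s_max = (
        spliced.groupby(labels).mean().max(axis=0)
    )
    u_max = unspliced.groupby(labels).mean().max(axis=0)
    keep = (s_max >= params.min_max_cluster_avg_spliced) & (
        u_max >= params.min_max_cluster_avg_unspliced
    )
    genes = [g for g in spliced.columns if keep[g]]
    if protein_coding is not None:
        genes = [g for g in genes if g in protein_coding]
    if not genes:
        raise ValueError("no gene passes the velocity expression filter")
    return genes


def pool_knn(
    spliced: pd.DataFrame,
    unspliced: pd.DataFrame,
    embedding: pd.DataFrame | np.ndarray,
    k_cells: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-pooled, size-normalized spliced/unspliced profiles.

    Each cell's counts are summed with its ``k_cells`` nearest neighbors in
    the embedding (Euclidean), then each layer is rescaled per cell to the
    median pooled depth of that layer.  ``k_cells = 0`` is identity pooling
    (plain size normalization).
    """
    n = len(spliced)
    if k_cells >= n:
        raise ValueError("k_cells must be below the number of cells")
    S = spliced.to_numpy(dtype=float)
    U = unspliced.to_numpy(dtype=float)
    if k_cells > 0:
        E = np.asarray(embedding, dtype=float)
        nn = NearestNeighbors(n_neighbors=k_cells + 1).fit(E)
        _, idx = nn.kneighbors(E)
        S = S[idx].sum(axis=1)
        U = U[idx].sum(axis=1)
    out = []
    for M in (S, U):
        tot = M.sum(axis=1)
        med = np.median(tot)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(tot[:, None] > 0, M / tot[:, None] * med, 0.0)
        out.append(norm)
    pooled_s = pd.DataFrame(out[0], index=spliced.index, columns=spliced.columns)
    pooled_u = pd.DataFrame(out[1], index=unspliced.index, columns=unspliced.columns)
    return pooled_s, pooled_u


def fit_gamma(
    pooled_s: pd.DataFrame, pooled_u: pd.DataFrame, fit_quantile: float = 0.5
) -> tuple[pd.Series, pd.Series]:
    """Per-gene gamma by zero-intercept least squares on the extreme-quantile
    cells: gamma = max(0, sum(U*S) / sum(S^2)) over cells whose S lies in the
    bottom or top ``fit_quantile`` of that gene's values.  Genes with all-zero
    selected S get gamma 0 and a degenerate flag.
    """
    if len(pooled_s) < 4:
        raise ValueError("at least 4 cells are required to fit gamma")
    S = pooled_s.to_numpy(dtype=float)
    U = pooled_u.to_numpy(dtype=float)
    lo = np.quantile(S, fit_quantile, axis=0)
    hi = np.quantile(S, 1.0 - fit_quantile, axis=0)
    sel = (S <= lo) | (S >= hi)
    ss = np.where(sel, S, 0.0)
    us = np.where(sel, U, 0.0)
    denom = (ss * ss).sum(axis=0)
    numer = (us * ss).sum(axis=0)
    degenerate = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(degenerate, 0.0, np.maximum(0.0, numer / np.where(denom == 0, 1.0, denom)))
    genes = pooled_s.columns
    return (
        pd.Series(gamma, index=genes, name="gamma"),
        pd.Series(degenerate, index=genes, name="degenerate"),
    )


def velocity_values(
    pooled_s: pd.DataFrame,
    pooled_u: pd.DataFrame,
    gamma: pd.Series,
    beta: float = 1.0,
) -> pd.DataFrame:
    """v_cg = beta * U_cg - gamma_g * S_cg, exactly."""
    if pooled_s.shape != pooled_u.shape:
        raise ValueError("spliced/unspliced shapes differ")
    g = gamma.reindex(pooled_s.columns).to_numpy()
    v = beta * pooled_u.to_numpy(dtype=float) - g[None, :] * pooled_s.to_numpy(dtype=float)
    return pd.DataFrame(v, index=pooled_s.index, columns=pooled_s.columns)


def perpendicular_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance of (x, y) from the identity line: |y - x| / sqrt(2)."""
    return np.abs(np.asarray(y) - np.asarray(x)) / math.sqrt(2.0)


def ds_genes(
    v: pd.DataFrame,
    condition: pd.Series,
    subtype_labels: pd.Series | np.ndarray,
    subtype: str,
    params: VelocityParams = VelocityParams(),
    spliced: pd.DataFrame | None = None,
    naive: str = "naive",
    inflamed: str = "inflamed",
) -> pd.DataFrame:
    """Differentially speeded genes of one subtype.

    x (resp. y) is the mean velocity over the subtype's naive (resp. inflamed)
    cells; when ``spliced`` is given both are divided by the gene's mean
    pooled spliced abundance over the subtype's cells (relative velocity).
    Records are sorted by perpendicular distance, descending; ``selected``
    flags d > ``params.ds_distance_min``.
    """
    labels = np.asarray(subtype_labels)
    in_st = labels == subtype
    naive_mask = in_st & (condition == naive).to_numpy()
    infl_mask = in_st & (condition == inflamed).to_numpy()
    if naive_mask.sum() == 0 or infl_mask.sum() == 0:
        raise ValueError(f"subtype {subtype!r} lacks cells in one condition")
    x = v.iloc[naive_mask].mean(axis=0)
    y = v.iloc[infl_mask].mean(axis=0)
    if spliced is not None:
        scale = spliced.iloc[in_st].mean(axis=0).clip(lower=1e-12)
        x = x / scale
        y = y / scale
    d = perpendicular_distance(x.to_numpy(), y.to_numpy())
    table = pd.DataFrame(
        {
            "gene": v.columns,
            "subtype": subtype,
            "x_naive": x.to_numpy(),
            "y_inflamed": y.to_numpy(),
            "distance": d,
            "side": np.where(y.to_numpy() >= x.to_numpy(), "above", "below"),
            "selected": d > params.ds_distance_min,
        }
    )
    table = table.iloc[
        np.lexsort((table["gene"], -table["distance"].to_numpy()))
    ].reset_index(drop=True)
    return table


def unspliced_residuals(
    pooled_s_g: pd.Series,
    pooled_u_g: pd.Series,
    gamma_g: float,
    condition: pd.Series,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-cell deviation of unspliced abundance from its steady-state
    expectation, ``r_c = U_c - gamma * S_c``, with per-condition means.
    Positive values indicate an expected up-regulation."""
    resid = pooled_u_g - gamma_g * pooled_s_g
    means = {
        str(cond): float(resid[(condition == cond).to_numpy()].mean())
        for cond in sorted(condition.unique())
    }
    return resid.rename("residual"), means


def de_ds_intersect(de_table: pd.DataFrame, ds_table: pd.DataFrame) -> set[str]:
    """Genes both significantly differentially expressed and selected as DS."""
    de = set(de_table.loc[de_table["significant"], "gene"])
    ds = set(ds_table.loc[ds_table["selected"], "gene"])
    return de & ds
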