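"""Cell-level quality control, normalization, HVG selection and cell-cycle adjustment.

The filtering mirrors standard plate-based scRNA-seq practice: cells are
dropped when their library size or detected-feature count lies more than
``mad_k`` median absolute deviations (MADs, scaled by 1.4826) from the median,
when their mitochondrial fraction lies ``mad_k`` MADs *above* the median, when
the library size falls outside a hard count window, when the combined
mitochondrial + ribosomal read fraction exceeds a cap (default 10%), or when
the pan-leukocyte marker Cd45 (*Ptprc*) is detected at all.  Expression is
total-count log-normalized, ``x = ln(1 + count / libsize * scale_factor)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .synthdata import CD45_GENE, MITO_GENES, RIBO_GENES

__all__ = [
    "QCParams",
    "QCEmptyError",
    "mad_outlier_filter",
    "apply_cell_filters",
    "qc_summary",
    "lognormalize",
    "select_hvg",
    "cell_cycle_scores",
    "regress_out",
]

MAD_CONSTANT = 1.4826  # normal-consistency scaling


class QCEmptyError(ValueError):
    """Raised when no cell survives filtering."""


@dataclass(frozen=True)
class QCParams:
    mad_k: float = 3.0
    count_min: float = 0.0
    count_max: float = float("inf")
    mito_max_frac: float = 0.10
    cd45_gene: str = CD45_GENE
    mito_genes: tuple[str, ...] = MITO_GENES
    ribo_genes: tuple[str, ...] = RIBO_GENES
    hvg_n: int = 2000
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")
        if not self.count_min < self.count_max:
            raise ValueError("count_min must be below count_max")
        if not 0 < self.mito_max_frac <= 1:
            raise ValueError("mito_max_frac must be in (0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    def with_count_window_from(
        self, libsizes: np.ndarray, q_low: float = 0.005, q_high: float = 0.995
    ) -> "QCParams":
        """Derive the hard count window from quantiles of the observed depth
        distribution (the analogue of an absolute read window for data whose
        depth scale is not known in advance)."""
        lo = float(np.quantile(libsizes, q_low))
        hi = float(np.quantile(libsizes, q_high))
        return replace(self, count_min=lo, count_max=hi)


def mad_outlier_filter(
    values: np.ndarray, k: float = 3.0, direction: str = "both"
) -> np.ndarray:
    """Boolean mask of MAD outliers (True = outlier).

    MAD is scaled by 1.4826; ``direction="both"`` flags ``|x - median| > k*MAD``,
    ``direction="upper"`` flags only ``x - median > k*MAD``.  When all values
    are identical the MAD is zero and, by convention, no cell is flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("at least 3 cells are required for the MAD filter")
    if direction not in ("both", "upper"):
        raise ValueError("direction must be 'both' or 'upper'")
    med = np.median(values)
    mad = MAD_CONSTANT * np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros(values.shape, dtype=bool)
    dev = values - med
    if direction == "both":
        return np.abs(dev) > k * mad
    return dev > k * mad


def _qc_metrics(adata: ad.AnnData, params: QCParams) -> pd.DataFrame:
    counts = np.asarray(adata.layers["spliced"])
    genes = adata.var_names
    mito = genes.isin(params.mito_genes)
    ribo = genes.isin(params.ribo_genes)
    lib = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, counts[:, mito].sum(axis=1) / lib, 0.0)
        mito_ribo_frac = np.where(
            lib > 0, counts[:, mito | ribo].sum(axis=1) / lib, 0.0
        )
    return pd.DataFrame(
        {
            "libsize": lib,
            "n_features": (counts > 0).sum(axis=1),
            "mito_frac": mito_frac,
            "mito_ribo_frac": mito_ribo_frac,
        },
        index=adata.obs_names,
    )


def apply_cell_filters(
    adata: ad.AnnData, params: QCParams
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply all cell filters; returns the filtered data and a per-cell report.

    The report holds each metric, one boolean column per filter
    (True = fails that filter) and the final ``keep`` flag, which is the
    conjunction of the individual verdicts — so the result does not depend on
    the order in which the filters are considered.
    """
    if params.cd45_gene not in adata.var_names:
        raise ValueError(f"Cd45 gene {params.cd45_gene!r} not in gene universe")
    report = _qc_metrics(adata, params)
    counts = np.asarray(adata.layers["spliced"])
    cd45 = counts[:, adata.var_names.get_loc(params.cd45_gene)]
    report["fail_libsize_mad"] = mad_outlier_filter(
        report["libsize"].to_numpy(), params.mad_k, "both"
    )
    report["fail_features_mad"] = mad_outlier_filter(
        report["n_features"].to_numpy(), params.mad_k, "both"
    )
    report["fail_mito_mad"] = mad_outlier_filter(
        report["mito_frac"].to_numpy(), params.mad_k, "upper"
    )
    report["fail_count_range"] = (report["libsize"] < params.count_min) | (
        report["libsize"] > params.count_max
    )
    report["fail_mito_cap"] = report["mito_ribo_frac"] > params.mito_max_frac
    report["fail_cd45"] = cd45 > 0
    fail_cols = [c for c in report.columns if c.startswith("fail_")]
    report["keep"] = ~report[fail_cols].any(axis=1)
    if not report["keep"].any():
        raise QCEmptyError("no cell survives quality filtering")
    return adata[report["keep"].to_numpy()].copy(), report


def qc_summary(report: pd.DataFrame) -> dict[str, int]:
    """Number of cells failing each filter plus total kept/dropped counts."""
    out = {c: int(report[c].sum()) for c in report.columns if c.startswith("fail_")}
    out["n_cells"] = int(len(report))
    out["n_kept"] = int(report["keep"].sum())
    out["n_dropped"] = out["n_cells"] - out["n_kept"]
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = 10_000.0) -> pd.DataFrame:
    """Total-count log-normalization of the spliced layer:
    ``x_cg = ln(1 + count_cg / libsize_c * scale_factor)``."""
    counts = np.asarray(adata.layers["spliced"], dtype=float)
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        bad = adata.obs_names[np.flatnonzero(lib == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero library size")
    norm = np.log1p(counts / lib[:, None] * scale_factor)
    return pd.DataFrame(norm, index=adata.obs_names, columns=adata.var_names)


def select_hvg(normalized: pd.DataFrame, n: int, n_bins: int = 20) -> list[str]:
    """Top-``n`` highly variable genes.

    Genes are ranked by their dispersion (variance/mean of the normalized
    expression) standardized within ``n_bins`` mean-expression bins; ties are
    broken by lexicographic gene id, so the result is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > normalized.shape[1]:
        raise ValueError("n exceeds the number of genes")
    mean = normalized.mean(axis=0)
    var = normalized.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    disp = pd.Series(disp, index=normalized.columns)
    # equal-occupancy bins over the mean; degenerate bins get z-score zero
    order = mean.rank(method="first")
    bins = np.ceil(order / (len(mean) / n_bins)).clip(1, n_bins).astype(int)
    z = pd.Series(0.0, index=normalized.columns)
    for b in range(1, n_bins + 1):
        in_bin = bins == b
        if in_bin.sum() == 0:
            continue
        d = disp[in_bin]
        sd = d.std(ddof=1)
        z[in_bin] = (d - d.mean()) / sd if sd and sd > 0 else 0.0
    order_idx = np.lexsort((normalized.columns.to_numpy(), -z.to_numpy()))
    return normalized.columns[order_idx][:n].tolist()


def cell_cycle_scores(
    normalized: pd.DataFrame,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """S and G2/M scores with expression-matched controls, plus a phase call.

    A set's score is the mean expression of the set minus the mean expression
    of ``n_ctrl`` control genes drawn (seeded) from each set gene's
    mean-expression bin.  Phase is G2M when the G2M score is the larger and
    positive, S when the S score is the larger and positive, else G1.
    """
    rng = np.random.default_rng(seed)
    present = {
        "S": [g for g in s_genes if g in normalized.columns],
        "G2M": [g for g in g2m_genes if g in normalized.columns],
    }
    for name, genes in present.items():
        if not genes:
            raise ValueError(f"{name} gene set entirely absent from the matrix")
    mean = normalized.mean(axis=0)
    order = mean.rank(method="first")
    bins = np.ceil(order / (len(mean) / n_bins)).clip(1, n_bins).astype(int)
    scores = {}
    for name in ("S", "G2M"):  # fixed order: S controls drawn first
        genes = present[name]
        ctrl: list[str] = []
        for g in sorted(genes):
            pool = normalized.columns[(bins == bins[g]).to_numpy()]
            ctrl.extend(rng.choice(pool, size=n_ctrl, replace=True))
        scores[name] = (
            normalized[genes].mean(axis=1) - normalized[ctrl].mean(axis=1)
        )
    out = pd.DataFrame({"S_score": scores["S"], "G2M_score": scores["G2M"]})
    phase = np.where(
        (out["G2M_score"] >= out["S_score"]) & (out["G2M_score"] > 0),
        "G2M",
        np.where((out["S_score"] > out["G2M_score"]) & (out["S_score"] > 0), "S", "G1"),
    )
    out["phase"] = phase
    return out


def regress_out(
    normalized: pd.DataFrame,
    covariates: np.ndarray | pd.DataFrame | None = None,
    clip: float = 10.0,
) -> pd.DataFrame:
    """Per-gene OLS residuals against the covariates (plus intercept), then
    per-gene standardization to mean 0 / unit variance, clipped at ``+-clip``.
    With no covariates this reduces to centering + scaling."""
    X = normalized.to_numpy(dtype=float)
    n = X.shape[0]
    if covariates is None:
        design = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0, ddof=1)
    # genes fitted (near-)exactly have no residual signal left; avoid blowing
    # float noise up to full scale
    tiny = sd <= 1e-10 * np.maximum(1.0, np.abs(X).max(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(~tiny & (sd > 0), resid / np.where(sd > 0, sd, 1.0), 0.0)
    scaled = np.clip(scaled, -clip, clip)
    return pd.DataFrame(scaled, index=normalized.index, columns=normalized.columns)
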