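"""PCA embedding, shared-nearest-neighbor clustering and LEC subtype annotation.

Clusters are found on a kNN graph reweighted by the Jaccard overlap of
neighbor sets (edges below 1/15 pruned), with seeded modularity optimization
(Leiden, RBConfiguration at the requested resolution) and size-ordered
relabeling for stable output.  Subtypes are called per cluster from
required-high / required-low marker rules (e.g. ceiling LECs: Ackr4 high with
Lyve1 low; floor LECs: Madcam1 and Lyve1 high; medullary LECs: Mrc1 and
Lyve1 high).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .diffexpr import wilcoxon_test, _log2_fold_change

__all__ = [
    "ClusterParams",
    "SubtypeRule",
    "DEFAULT_SUBTYPE_RULES",
    "embed_pca",
    "snn_cluster",
    "annotate_subtypes",
    "conserved_markers",
]


@dataclass(frozen=True)
class ClusterParams:
    n_pcs: int = 20
    knn_k: int = 20
    resolution: float = 0.5
    batch_key: str | None = None
    snn_prune: float = 1.0 / 15.0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be at least 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass(frozen=True)
class SubtypeRule:
    label: str
    high: tuple[str, ...]
    low: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise ValueError(f"rule {self.label!r}: high/low gene sets overlap")


DEFAULT_SUBTYPE_RULES: tuple[SubtypeRule, ...] = (
    SubtypeRule("floor", high=("Madcam1", "Lyve1")),
    SubtypeRule("ceiling", high=("Ackr4",), low=("Lyve1",)),
    SubtypeRule("medullary", high=("Mrc1", "Lyve1")),
)


def center_batches(adjusted: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Per-batch gene centering (the light-weight substitute for anchor
    integration when batch structure is a scalar depth shift)."""
    out = adjusted.copy()
    for b in sorted(batches.unique()):
        mask = (batches == b).to_numpy()
        out.iloc[mask] = adjusted.iloc[mask] - adjusted.iloc[mask].mean(axis=0)
    return out


def embed_pca(
    adjusted: pd.DataFrame, hvg: Sequence[str] | None = None, n_pcs: int = 20
) -> pd.DataFrame:
    """PC scores of the centered (HVG-restricted) matrix.

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so the embedding is deterministic.
    """
    X = adjusted[list(hvg)] if hvg is not None else adjusted
    if n_pcs > min(X.shape):
        raise ValueError("n_pcs exceeds min(cells, genes)")
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    scores = U[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        scores, index=adjusted.index, columns=[f"PC{j + 1}" for j in range(n_pcs)]
    )


def _snn_graph(scores: np.ndarray, knn_k: int, prune: float) -> sp.csr_matrix:
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=knn_k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # each row includes the cell itself
    rows = np.repeat(np.arange(n), knn_k + 1)
    member = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (member @ member.T).tocoo()  # |N_i & N_j|
    size = knn_k + 1
    jac = shared.data / (2 * size - shared.data)
    keep = jac >= prune
    snn = sp.coo_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    snn.setdiag(0)
    snn.eliminate_zeros()
    return snn.tocsr()


def snn_cluster(
    scores: pd.DataFrame | np.ndarray,
    knn_k: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
) -> np.ndarray:
    """Cluster labels (ints, 0 = largest cluster) from the SNN graph."""
    index = scores.index if isinstance(scores, pd.DataFrame) else None
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if n < knn_k + 1:
        raise ValueError("need at least knn_k + 1 cells")
    snn = _snn_graph(X, knn_k, prune)
    coo = sp.triu(snn, k=1).tocoo()
    g = ig.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    # deterministic relabeling: decreasing cluster size, ties by old label
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels])
    if index is not None:
        return pd.Series(labels, index=index, name="cluster").to_numpy()
    return labels


def annotate_subtypes(
    labels: np.ndarray,
    normalized: pd.DataFrame,
    rules: Sequence[SubtypeRule] = DEFAULT_SUBTYPE_RULES,
) -> dict[int, str]:
    """Assign each cluster the best-scoring rule (mean(high) - mean(low) on the
    cluster-average normalized expression); "unassigned" when no rule scores
    above zero.  Invariant to the order of the rules and of the cells."""
    for rule in rules:
        for g in rule.high + rule.low:
            if g not in normalized.columns:
                raise ValueError(f"rule gene {g!r} missing from the matrix")
    labels = np.asarray(labels)
    out: dict[int, str] = {}
    for cl in sorted(set(labels.tolist())):
        profile = normalized.iloc[labels == cl].mean(axis=0)
        best_label, best_score = "unassigned", 0.0
        for rule in sorted(rules, key=lambda r: r.label):
            score = profile[list(rule.high)].mean()
            if rule.low:
                score -= profile[list(rule.low)].mean()
            if score > best_score:
                best_label, best_score = rule.label, score
        out[cl] = best_label
    return out


def conserved_markers(
    normalized: pd.DataFrame,
    labels: np.ndarray,
    condition: pd.Series,
    cluster: int,
    top_k: int = 10,
) -> pd.DataFrame:
    """Markers of ``cluster`` vs the rest that hold in every condition.

    Within each condition a Wilcoxon rank-sum test of cluster vs rest is run
    per gene; the combined p is the max over conditions and genes are ranked
    by combined p, then by the smaller of the per-condition log2 fold changes
    (descending), then by gene id.  Returns the ``top_k`` rows.
    """
    labels = np.asarray(labels)
    conds = sorted(condition.unique())
    in_cl = labels == cluster
    for cond in conds:
        if not (in_cl & (condition == cond).to_numpy()).any():
            raise ValueError(f"cluster {cluster} absent in condition {cond!r}")
    records = []
    X = normalized.to_numpy()
    for gi, gene in enumerate(normalized.columns):
        p_max, lfc_min = 0.0, np.inf
        for cond in conds:
            cmask = (condition == cond).to_numpy()
            x = X[cmask & in_cl, gi]
            y = X[cmask & ~in_cl, gi]
            _, p = wilcoxon_test(x, y)
            p_max = max(p_max, p)
            lfc_min = min(lfc_min, _log2_fold_change(x, y))
        records.append({"gene": gene, "cluster": cluster, "p_combined": p_max,
                        "min_log2fc": lfc_min})
    table = pd.DataFrame(records)
    table = table.iloc[
        np.lexsort(
            (table["gene"], -table["min_log2fc"].to_numpy(), table["p_combined"].to_numpy())
        )
    ].reset_index(drop=True)
    return table.head(top_k)
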