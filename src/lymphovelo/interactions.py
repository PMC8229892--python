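"""Ligand-receptor crosstalk screening by a cluster-label permutation test.

For every (pair, sender, receiver) combination the interaction mean is the
average of the ligand's mean expression in the sender cluster and the
receptor's mean expression in the receiver cluster.  A null distribution is
built by reshuffling the cluster labels; the empirical p-value uses +1
smoothing, ``p = (1 + #{null >= observed}) / (1 + n_perm)``.  Pairs whose
ligand (in the sender) or receptor (in the receiver) is detected in fewer
than ``threshold`` of the cells are assigned p = 1.  Protein complexes are
scored per cell by the minimum expression over their member genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LRPair",
    "InteractionParams",
    "map_orthologs",
    "permutation_test",
    "interaction_counts",
    "intersect_with_de",
]

RECORD_COLUMNS = [
    "pair", "sender", "receiver", "interaction_mean", "p",
    "frac_ligand", "frac_receptor", "significant",
]


@dataclass(frozen=True)
class LRPair:
    pair_id: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError(f"pair {self.pair_id!r}: ligand/receptor sets must be non-empty")


@dataclass(frozen=True)
class InteractionParams:
    n_perm: int = 1000
    threshold: float = 0.1  # minimum expressed-cell fraction per side
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")


def read_lr_pairs(path) -> list[LRPair]:
    """TSV with columns pair_id, ligand, receptor; complex members joined by '+'."""
    table = pd.read_csv(path, sep="\t")
    return [
        LRPair(
            str(r["pair_id"]),
            tuple(str(r["ligand"]).split("+")),
            tuple(str(r["receptor"]).split("+")),
        )
        for _, r in table.iterrows()
    ]


def map_orthologs(
    genes: list[str], table: pd.DataFrame
) -> tuple[dict[str, str], int]:
    """Mouse -> human symbol mapping from a two-column lookup table.

    One-to-one rows map directly; one-to-many rows are resolved in favor of
    the uppercased mouse symbol when present, else dropped.  Returns the
    mapping and the number of input genes left unmapped.
    """
    if table.empty:
        raise ValueError("empty ortholog mapping table")
    cols = list(table.columns[:2])
    lookup: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        lookup.setdefault(str(row[cols[0]]), []).append(str(row[cols[1]]))
    mapping: dict[str, str] = {}
    dropped = 0
    for g in genes:
        targets = lookup.get(g)
        if not targets:
            dropped += 1
            continue
        if len(set(targets)) == 1:
            mapping[g] = targets[0]
        elif g.upper() in targets:
            mapping[g] = g.upper()
        else:
            dropped += 1
    return mapping, dropped


def _complex_values(normalized: pd.DataFrame, members: tuple[str, ...]) -> np.ndarray:
    missing = [g for g in members if g not in normalized.columns]
    if missing:
        raise ValueError(f"pair member gene(s) missing from matrix: {missing}")
    return normalized[list(members)].to_numpy().min(axis=1)


def permutation_test(
    normalized: pd.DataFrame,
    cluster_labels: pd.Series | np.ndarray,
    pairs: list[LRPair],
    n_perm: int = 1000,
    threshold: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Interaction records for every ordered cluster pair and LR pair."""
    labels = pd.Series(np.asarray(cluster_labels), index=normalized.index)
    sizes = labels.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"clusters with < 2 cells excluded: {small}")
        keep = ~labels.isin(small).to_numpy()
        normalized = normalized.iloc[keep]
        labels = labels.iloc[keep]
    clusters = sorted(labels.unique().tolist())
    if len(clusters) < 2:
        raise ValueError("at least 2 clusters are required")
    rng = np.random.default_rng(seed)
    n_cells = len(normalized)
    # cells x (2 * n_pairs): ligand columns then receptor columns
    lig = np.column_stack([_complex_values(normalized, p.ligand) for p in pairs])
    rec = np.column_stack([_complex_values(normalized, p.receptor) for p in pairs])
    lab_codes = pd.Categorical(labels, categories=clusters).codes
    n_cl = len(clusters)
    onehot = np.zeros((n_cl, n_cells))
    onehot[lab_codes, np.arange(n_cells)] = 1.0
    group_n = onehot.sum(axis=1, keepdims=True)
    mean_of = lambda M: (onehot @ M) / group_n  # clusters x pairs

    lig_mean, rec_mean = mean_of(lig), mean_of(rec)
    lig_frac, rec_frac = mean_of((lig > 0).astype(float)), mean_of((rec > 0).astype(float))
    # observed interaction means for all ordered (sender, receiver) pairs
    obs = 0.5 * (lig_mean[:, None, :] + rec_mean[None, :, :])  # s x r x pairs
    exceed = np.zeros_like(obs, dtype=np.int64)
    perm_codes = lab_codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_codes)
        oh = np.zeros((n_cl, n_cells))
        oh[perm_codes, np.arange(n_cells)] = 1.0
        gn = oh.sum(axis=1, keepdims=True)
        lm = (oh @ lig) / gn
        rm = (oh @ rec) / gn
        null = 0.5 * (lm[:, None, :] + rm[None, :, :])
        exceed += null >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for si, s in enumerate(clusters):
        for ri, r in enumerate(clusters):
            for pi, pair in enumerate(pairs):
                fl = lig_frac[si, pi]
                fr = rec_frac[ri, pi]
                expressed = fl >= threshold and fr >= threshold
                p = pvals[si, ri, pi] if expressed else 1.0
                rows.append(
                    {
                        "pair": pair.pair_id,
                        "sender": s,
                        "receiver": r,
                        "interaction_mean": obs[si, ri, pi],
                        "p": p,
                        "frac_ligand": fl,
                        "frac_receptor": fr,
                        "significant": bool(expressed and p <= alpha),
                    }
                )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def interaction_counts(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Significant-interaction counts per ordered (sender, receiver) cluster
    pair, plus the log2(count + 1) companion matrix used for heatmaps."""
    clusters = sorted(set(records["sender"]) | set(records["receiver"]))
    counts = pd.DataFrame(0, index=clusters, columns=clusters)
    sig = records[records["significant"]]
    for (s, r), group in sig.groupby(["sender", "receiver"]):
        counts.loc[s, r] = len(group)
    return counts, np.log2(counts + 1.0)


def intersect_with_de(
    records: pd.DataFrame,
    pairs: list[LRPair],
    de_table: pd.DataFrame,
    lec_clusters: set | None = None,
) -> pd.DataFrame:
    """Flag records whose ligand (sender side) or receptor (receiver side) is a
    significant DE gene, carrying the DE direction.  When ``lec_clusters`` is
    given, only sides whose cluster is an LEC cluster are checked."""
    sig = de_table.loc[de_table["significant"].astype(bool)]
    direction = dict(zip(sig["gene"], sig["direction"]))
    by_id = {p.pair_id: p for p in pairs}
    out = records.copy()
    de_genes, de_dirs = [], []
    for _, row in out.iterrows():
        pair = by_id[row["pair"]]
        hits: list[tuple[str, str]] = []
        for members, cluster in ((pair.ligand, row["sender"]), (pair.receptor, row["receiver"])):
            if lec_clusters is not None and cluster not in lec_clusters:
                continue
            for g in members:
                if g in direction:
                    hits.append((g, direction[g]))
        de_genes.append(hits[0][0] if hits else "")
        de_dirs.append(hits[0][1] if hits else "")
    out["de_gene"] = de_genes
    out["de_direction"] = de_dirs
    out["de_flag"] = out["de_gene"] != ""
    return out
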