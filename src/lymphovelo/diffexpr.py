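"""Wilcoxon rank-sum differential expression with expression-fraction and
fold-change filters, DE-set overlaps, and a hypergeometric gene-set test.

Per-subtype two-condition DE follows the plate-seq convention: genes are
pre-filtered to those detected in at least ``min_pct`` of the cells of either
condition, tested with a two-sided Wilcoxon rank-sum on log-normalized values,
Bonferroni-adjusted over the tested genes within the subtype, and reported as
up/down when ``|log2FC| > logfc_min`` and ``p_adj < alpha_adj``.  The log2
fold change is computed on de-logged means with a pseudocount of one:
``log2((mean(expm1 x_case) + 1) / (mean(expm1 x_ctrl) + 1))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEParams",
    "wilcoxon_test",
    "de_by_subtype",
    "significant_genes",
    "de_overlap",
    "geneset_enrichment",
]

DE_COLUMNS = [
    "gene", "subtype", "log2fc", "pct_case", "pct_ctrl",
    "p", "p_adj", "direction", "significant",
]


@dataclass(frozen=True)
class DEParams:
    min_pct: float = 0.2
    logfc_min: float = 0.2
    alpha_adj: float = 0.05
    adjust: str = "bonferroni"  # or "bh"

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must be in [0, 1]")
        if self.logfc_min < 0:
            raise ValueError("logfc_min must be non-negative")
        if not 0 < self.alpha_adj < 1:
            raise ValueError("alpha_adj must be in (0, 1)")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValueError("adjust must be 'bonferroni' or 'bh'")


def _rank_sum_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U statistic of x, its null mean, and tie-corrected null SD."""
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, t = np.unique(combined, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return float(u1), mu, math.sqrt(max(var, 0.0))


def wilcoxon_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks handle ties.  For fewer than 8 observations in total the null
    distribution of U is enumerated exactly over all group assignments of the
    observed (possibly tied) values; otherwise a normal approximation with
    tie-corrected variance and a 0.5 continuity correction is used.  When all
    values are identical across both groups p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u1, mu, sd = _rank_sum_stat(x, y)
    n1, n2 = len(x), len(y)
    if sd == 0.0:
        return u1, 1.0
    if n1 + n2 < 8:
        combined = np.concatenate([x, y])
        ranks = stats.rankdata(combined)
        obs_dev = abs(u1 - mu)
        offset = n1 * (n1 + 1) / 2.0
        hits = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - offset
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                hits += 1
        return u1, hits / total
    z = (abs(u1 - mu) - 0.5) / sd
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return u1, p


def _log2_fold_change(x: np.ndarray, y: np.ndarray) -> float:
    """log2 ratio of de-logged means with pseudocount 1 (Seurat >= 4 style)."""
    return float(
        np.log2((np.expm1(x).mean() + 1.0) / (np.expm1(y).mean() + 1.0))
    )


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    return stats.false_discovery_control(p, method="bh")


def de_by_subtype(
    normalized: pd.DataFrame,
    subtype_labels: pd.Series,
    condition: pd.Series,
    params: DEParams = DEParams(),
    case: str = "inflamed",
    control: str = "naive",
    counts: pd.DataFrame | None = None,
    subtypes: list[str] | None = None,
) -> pd.DataFrame:
    """Condition-wise DE within each subtype; returns one row per tested gene.

    Detection fractions (``pct_case``/``pct_ctrl``) are computed on raw counts
    when given, else on the support of the normalized values (identical sets).
    """
    detected = (counts if counts is not None else normalized) > 0
    if subtypes is None:
        subtypes = sorted(set(subtype_labels) - {"unassigned"})
    tables = []
    for st in subtypes:
        in_st = (subtype_labels == st).to_numpy()
        case_mask = in_st & (condition == case).to_numpy()
        ctrl_mask = in_st & (condition == control).to_numpy()
        if case_mask.sum() == 0 or ctrl_mask.sum() == 0:
            raise ValueError(f"subtype {st!r} missing cells in one condition")
        pct_case = detected.iloc[case_mask].mean(axis=0)
        pct_ctrl = detected.iloc[ctrl_mask].mean(axis=0)
        tested = normalized.columns[
            np.maximum(pct_case, pct_ctrl) >= params.min_pct
        ]
        if len(tested) == 0:
            tables.append(pd.DataFrame(columns=DE_COLUMNS))
            continue
        rows = []
        Xc = normalized.loc[case_mask, tested].to_numpy()
        Xn = normalized.loc[ctrl_mask, tested].to_numpy()
        for gi, gene in enumerate(tested):
            _, p = wilcoxon_test(Xc[:, gi], Xn[:, gi])
            lfc = _log2_fold_change(Xc[:, gi], Xn[:, gi])
            rows.append(
                {
                    "gene": gene,
                    "subtype": st,
                    "log2fc": lfc,
                    "pct_case": float(pct_case[gene]),
                    "pct_ctrl": float(pct_ctrl[gene]),
                    "p": p,
                }
            )
        table = pd.DataFrame(rows)
        table["p_adj"] = _adjust(table["p"].to_numpy(), params.adjust)
        table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
        table["significant"] = (np.abs(table["log2fc"]) > params.logfc_min) & (
            table["p_adj"] < params.alpha_adj
        )
        tables.append(table[DE_COLUMNS])
    return pd.concat(tables, ignore_index=True)


def significant_genes(table: pd.DataFrame, subtype: str, direction: str | None = None) -> set[str]:
    mask = (table["subtype"] == subtype) & table["significant"]
    if direction is not None:
        mask &= table["direction"] == direction
    return set(table.loc[mask, "gene"])


def de_overlap(tables: list[pd.DataFrame], names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise and overall intersection/union counts (and Jaccard) of the
    significant gene sets, per direction."""
    if len(tables) < 2:
        raise ValueError("at least two DE tables are required")
    if names is None:
        names = [f"t{i}" for i in range(len(tables))]
    sets = {
        (name, d): set(t.loc[t["significant"] & (t["direction"] == d), "gene"])
        for name, t in zip(names, tables)
        for d in ("up", "down")
    }
    rows = []
    for d in ("up", "down"):
        for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
            sa, sb = sets[(a, d)], sets[(b, d)]
            inter, union = len(sa & sb), len(sa | sb)
            rows.append(
                {
                    "direction": d, "set_a": a, "set_b": b,
                    "n_a": len(sa), "n_b": len(sb),
                    "intersection": inter, "union": union,
                    "jaccard": inter / union if union else 0.0,
                }
            )
        all_sets = [sets[(name, d)] for name in names]
        inter = len(set.intersection(*all_sets))
        union = len(set.union(*all_sets))
        rows.append(
            {
                "direction": d, "set_a": "all", "set_b": "all",
                "n_a": sum(len(s) for s in all_sets), "n_b": np.nan,
                "intersection": inter, "union": union,
                "jaccard": inter / union if union else 0.0,
            }
        )
    return pd.DataFrame(rows)


def geneset_enrichment(
    de_genes: set[str],
    background: set[str],
    sets: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Gene sets are intersected with the background; ``p`` is the upper tail
    P(overlap >= observed).  Rows are sorted by p; ``significant`` flags
    ``p < alpha``.
    """
    if not background:
        raise ValueError("background gene set is empty")
    de = set(de_genes) & set(background)
    if de != set(de_genes):
        raise ValueError("de_genes must be a subset of background")
    M, N = len(background), len(de)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & set(background)
        K = len(members)
        k = len(members & de)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append(
            {"set": name, "n_set": K, "overlap": k, "p": p, "significant": p < alpha}
        )
    table = pd.DataFrame(rows)
    return table.iloc[np.lexsort((table["set"], table["p"].to_numpy()))].reset_index(
        drop=True
    )
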