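"""Synthetic spliced/unspliced single-cell count generator with a ground-truth ledger.

Emulates Smart-seq2-like deep-count data for lymph-node lymphatic endothelial
cell (LEC) subtypes — subcapsular-sinus floor, subcapsular-sinus ceiling and
medullary-sinus LECs — under a naive and an inflamed condition.  Counts are
drawn from a negative-binomial model with per-cell depth factors; the unspliced
layer is generated at steady state, ``E[U] = gamma_g * E[S]``, so that the
degradation/splicing ratio gamma of each gene is recoverable by regression of
unspliced on spliced abundance.  The generator plants, and records in a
:class:`GroundTruth` ledger,

* subtype marker genes (fold-change in one subtype),
* condition-wise differential-expression (DE) effects (log2 fold change in the
  up-regulated condition, per subtype),
* unspliced-excess "differentially speeded" (DS) effects (a multiplier on the
  unspliced mean in the inflamed condition only, per subtype),
* a mitochondrial gene block whose summed count fraction is Beta-distributed
  (with an optional block of planted high-mitochondria cells),
* CD45(Ptprc)-expressing contaminant cells, and
* optional extra labelled cell types (stand-ins for the other lymph-node
  populations used by the ligand-receptor module).

All randomness flows through a single integer seed; regeneration with the same
config is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_dataset",
    "write_dataset",
    "default_config",
    "MITO_GENES",
    "RIBO_GENES",
    "CD45_GENE",
]

# Dedicated gene blocks of the default universe.  Mitochondrial transcripts
# carry no planted effects; their summed fraction per cell follows a Beta law
# so the 3-MAD mitochondria filter has something to act on.
MITO_GENES: tuple[str, ...] = (
    "mt-Nd1", "mt-Nd2", "mt-Nd3", "mt-Co1", "mt-Co2",
    "mt-Co3", "mt-Atp6", "mt-Atp8", "mt-Cytb", "mt-Nd4",
)
RIBO_GENES: tuple[str, ...] = (
    "Rpl3", "Rpl4", "Rpl5", "Rpl7", "Rps3",
    "Rps4x", "Rps6", "Rps7", "Rps8", "Rps9",
)
CD45_GENE = "Ptprc"

# Canonical LN LEC subtype markers (floor: Madcam1/Lyve1/Glycam1/Ccl20;
# ceiling: Ackr4, Lyve1-low; medullary: Mrc1/Lyve1/Marco) plus genes used by
# the worked examples (Cd200, Fn1, Jam3, the Ccl20-Ccr6 ligand-receptor pair).
_NAMED_GENES: tuple[str, ...] = (
    "Madcam1", "Lyve1", "Glycam1", "Ccl20", "Itga2b", "Coch", "Cd44",
    "Ackr4", "Anxa2", "Ccr6",
    "Mrc1", "Marco", "Reln",
    "Cd200", "Fn1", "Jam3", "Cxcl16", "Bst2",
)


def _gene_universe(n_genes: int) -> list[str]:
    special = list(MITO_GENES) + list(RIBO_GENES) + [CD45_GENE] + list(_NAMED_GENES)
    if n_genes < len(special) + 10:
        raise ValueError(f"n_genes must be at least {len(special) + 10}")
    generic = [f"g{i:04d}" for i in range(n_genes - len(special))]
    return special + generic


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset.

    ``marker_spec`` maps subtype -> [(gene, fold_change > 1)], ``de_spec`` maps
    subtype -> [(gene, log2_fold_change, up_condition)] and ``ds_spec`` maps
    subtype -> [(gene, unspliced_multiplier > 0)] (multiplier applied in the
    inflamed condition only).  ``gamma_range`` draws per-gene gamma values
    log-uniformly; ``gamma_true`` overrides individual genes.
    """

    n_cells_per_subtype_per_condition: int = 60
    n_genes: int = 1000
    subtype_names: tuple[str, ...] = ("floor", "ceiling", "medullary")
    conditions: tuple[str, str] = ("naive", "inflamed")
    marker_spec: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    de_spec: Mapping[str, Sequence[tuple[str, float, str]]] = field(default_factory=dict)
    ds_spec: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    gamma_range: tuple[float, float] = (0.05, 0.5)
    gamma_true: Mapping[str, float] = field(default_factory=dict)
    depth_mean: float = 30_000.0
    depth_cv: float = 0.3
    dispersion: float = 0.1
    mito_frac_mean: float = 0.05
    mito_frac_concentration: float = 60.0
    n_high_mito_cells: int = 0
    high_mito_frac: float = 0.5
    n_contaminant_cells: int = 0
    batch_names: tuple[str, ...] = ("b1", "b2")
    batch_depth_factor: float = 1.1
    extra_celltype_spec: Mapping[str, tuple[int, Sequence[tuple[str, float]]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_subtype_per_condition <= 0:
            raise ValueError("n_cells_per_subtype_per_condition must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        universe = set(self.gene_names())
        if len(universe) != self.n_genes:
            raise ValueError("duplicate gene names in universe")
        for name, entries in self.marker_spec.items():
            if name not in self.subtype_names:
                raise ValueError(f"marker_spec subtype {name!r} unknown")
            for gene, fc in entries:
                if gene not in universe:
                    raise ValueError(f"marker gene {gene!r} not in gene universe")
                if fc <= 0:
                    raise ValueError(f"marker fold-change for {gene!r} must be positive")
        for name, de_entries in self.de_spec.items():
            if name not in self.subtype_names:
                raise ValueError(f"de_spec subtype {name!r} unknown")
            for gene, _l2fc, cond in de_entries:
                if gene not in universe:
                    raise ValueError(f"DE gene {gene!r} not in gene universe")
                if cond not in self.conditions:
                    raise ValueError(f"DE condition {cond!r} unknown")
        for name, ds_entries in self.ds_spec.items():
            if name not in self.subtype_names:
                raise ValueError(f"ds_spec subtype {name!r} unknown")
            for gene, mult in ds_entries:
                if gene not in universe:
                    raise ValueError(f"DS gene {gene!r} not in gene universe")
                if mult <= 0:
                    raise ValueError(f"DS multiplier for {gene!r} must be positive")
        for gene in self.gamma_true:
            if gene not in universe:
                raise ValueError(f"gamma_true gene {gene!r} not in gene universe")
        if self.gamma_range[0] <= 0 or self.gamma_range[1] < self.gamma_range[0]:
            raise ValueError("gamma_range must be positive and ordered")
        if not 0 < self.mito_frac_mean < 1:
            raise ValueError("mito_frac_mean must be in (0, 1)")
        if self.n_contaminant_cells < 0 or self.n_high_mito_cells < 0:
            raise ValueError("cell counts must be non-negative")

    def gene_names(self) -> list[str]:
        return _gene_universe(self.n_genes)


@dataclass
class GroundTruth:
    """Ledger of the effects planted by :func:`generate_dataset`."""

    true_subtype: pd.Series  # per-cell label; contaminants labelled "contaminant"
    true_de_genes: dict[tuple[str, str], set[str]]  # (subtype, "up"/"down") -> genes
    true_ds_genes: dict[str, set[str]]  # subtype -> genes
    gamma_true: pd.Series  # per-gene gamma
    contaminant_cells: set[str]

    def to_dir(self, path: Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.true_subtype.rename("true_subtype").rename_axis("cell").reset_index().to_csv(
            path / "truth_subtypes.tsv", sep="\t", index=False
        )
        rows = [
            {"subtype": st, "direction": d, "gene": g}
            for (st, d), genes in sorted(self.true_de_genes.items())
            for g in sorted(genes)
        ]
        pd.DataFrame(rows, columns=["subtype", "direction", "gene"]).to_csv(
            path / "truth_de_genes.tsv", sep="\t", index=False
        )
        rows = [
            {"subtype": st, "gene": g}
            for st, genes in sorted(self.true_ds_genes.items())
            for g in sorted(genes)
        ]
        pd.DataFrame(rows, columns=["subtype", "gene"]).to_csv(
            path / "truth_ds_genes.tsv", sep="\t", index=False
        )
        self.gamma_true.rename("gamma").rename_axis("gene").reset_index().to_csv(
            path / "truth_gamma.tsv", sep="\t", index=False
        )
        pd.DataFrame({"cell": sorted(self.contaminant_cells)}).to_csv(
            path / "truth_contaminants.tsv", sep="\t", index=False
        )

    @classmethod
    def from_dir(cls, path: Path) -> "GroundTruth":
        path = Path(path)
        sub = pd.read_csv(path / "truth_subtypes.tsv", sep="\t").set_index("cell")["true_subtype"]
        de = pd.read_csv(path / "truth_de_genes.tsv", sep="\t")
        de_map: dict[tuple[str, str], set[str]] = {}
        for _, row in de.iterrows():
            de_map.setdefault((row["subtype"], row["direction"]), set()).add(row["gene"])
        ds = pd.read_csv(path / "truth_ds_genes.tsv", sep="\t")
        ds_map: dict[str, set[str]] = {}
        for _, row in ds.iterrows():
            ds_map.setdefault(row["subtype"], set()).add(row["gene"])
        gamma = pd.read_csv(path / "truth_gamma.tsv", sep="\t").set_index("gene")["gamma"]
        cont = pd.read_csv(path / "truth_contaminants.tsv", sep="\t")
        return cls(sub, de_map, ds_map, gamma, set(cont["cell"].tolist()))


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions: 3 subtypes x 2 conditions x 60 cells,
    1000 genes, planted markers (fold-change >= 4), DE effects (|log2FC| = 2,
    10 up and 10 down per subtype) and DS effects (unspliced x3 in inflamed,
    10 genes per subtype), 5 high-mitochondria cells and 10 CD45+ contaminants.
    """
    # Each subtype carries its canonical markers plus a broader expression
    # program (30 generic genes at fold-change 4), mirroring the fact that
    # real LEC subtypes differ by hundreds of genes, not a handful.
    marker_spec = {
        "floor": [("Madcam1", 8.0), ("Lyve1", 6.0), ("Glycam1", 8.0),
                  ("Ccl20", 8.0), ("Itga2b", 4.0), ("Coch", 4.0)]
        + [(f"g{i:04d}", 4.0) for i in range(300, 330)],
        "ceiling": [("Ackr4", 8.0), ("Anxa2", 4.0), ("Ccr6", 8.0)]
        + [(f"g{i:04d}", 4.0) for i in range(330, 360)],
        "medullary": [("Mrc1", 8.0), ("Lyve1", 6.0), ("Marco", 8.0), ("Reln", 4.0)]
        + [(f"g{i:04d}", 4.0) for i in range(360, 390)],
    }
    de_spec = {
        "floor": (
            [("Cd200", 2.0, "inflamed"), ("Fn1", 2.0, "inflamed")]
            + [(f"g{i:04d}", 2.0, "inflamed") for i in range(100, 108)]
            + [("Jam3", -2.0, "inflamed")]
            + [(f"g{i:04d}", -2.0, "inflamed") for i in range(110, 119)]
        ),
        "ceiling": (
            [(f"g{i:04d}", 2.0, "inflamed") for i in range(120, 130)]
            + [(f"g{i:04d}", -2.0, "inflamed") for i in range(130, 140)]
        ),
        "medullary": (
            [(f"g{i:04d}", 2.0, "inflamed") for i in range(140, 150)]
            + [(f"g{i:04d}", -2.0, "inflamed") for i in range(150, 160)]
        ),
    }
    ds_spec = {
        "floor": [("Cd200", 3.0)] + [(f"g{i:04d}", 3.0) for i in range(200, 209)],
        "ceiling": [(f"g{i:04d}", 3.0) for i in range(210, 220)],
        "medullary": [(f"g{i:04d}", 3.0) for i in range(220, 230)],
    }
    # Genes about to change expression carry a solid unspliced pool; give the
    # planted DS genes a representative gamma so the shift is observable.
    gamma_true = {g: 0.3 for entries in ds_spec.values() for g, _ in entries}
    cfg = SimConfig(
        marker_spec=marker_spec,
        de_spec=de_spec,
        ds_spec=ds_spec,
        gamma_true=gamma_true,
        n_high_mito_cells=5,
        n_contaminant_cells=10,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _planted_genes(config: SimConfig) -> tuple[set[str], set[str]]:
    """(marker genes, effect genes): markers are floored at a *low* baseline
    (so "required-low" annotation rules have contrast), DE/DS genes at the
    median baseline (so their effects are observable)."""
    markers: set[str] = set()
    for entries in config.marker_spec.values():
        markers.update(g for g, _ in entries)
    for _, mk in config.extra_celltype_spec.values():
        markers.update(g for g, _ in mk)
    effects: set[str] = set()
    for de_entries in config.de_spec.values():
        effects.update(g for g, _, _ in de_entries)
    for ds_entries in config.ds_spec.values():
        effects.update(g for g, _ in ds_entries)
    return markers, effects


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = m + dispersion * m^2 (dispersion -> 0: Poisson)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_dataset(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a layered count matrix and its ground-truth ledger.

    Returns an AnnData (cells x genes) whose ``X`` and ``layers["spliced"]``
    hold spliced counts and ``layers["unspliced"]`` unspliced counts, with
    ``obs`` columns ``condition`` and ``batch``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    mito_idx = np.array([gene_idx[g] for g in MITO_GENES])
    cd45_i = gene_idx[CD45_GENE]

    # Baseline relative abundance; mitochondrial block and Cd45 are handled
    # separately; planted genes are floored at the median so effects are
    # observable on top of them.
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    base[mito_idx] = 0.0
    base[cd45_i] = 0.0
    marker_genes, effect_genes = _planted_genes(config)
    for g in effect_genes:
        base[gene_idx[g]] = max(base[gene_idx[g]], 1.0)
    # canonical markers are near-absent outside their compartment
    for g in marker_genes - effect_genes:
        base[gene_idx[g]] = min(max(base[gene_idx[g]], 0.04), 0.08)
    mito_weights = rng.lognormal(0.0, 0.5, size=len(mito_idx))
    mito_weights /= mito_weights.sum()

    lo, hi = config.gamma_range
    gamma = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_genes))
    for g, val in config.gamma_true.items():
        gamma[gene_idx[g]] = val

    # --- cell roster ---------------------------------------------------
    cell_rows: list[dict] = []
    n_per = config.n_cells_per_subtype_per_condition
    for subtype in config.subtype_names:
        for condition in config.conditions:
            for _ in range(n_per):
                cell_rows.append({"subtype": subtype, "condition": condition})
    for name, (n_cells, _markers) in config.extra_celltype_spec.items():
        for j in range(n_cells):
            cell_rows.append({"subtype": name, "condition": config.conditions[j % 2]})
    for j in range(config.n_contaminant_cells):
        cell_rows.append({"subtype": "contaminant", "condition": config.conditions[j % 2]})
    n_cells = len(cell_rows)
    for i, row in enumerate(cell_rows):
        row["cell"] = f"c{i:04d}"
        row["batch"] = config.batch_names[i % len(config.batch_names)]

    # --- per-cell expected spliced profiles ----------------------------
    marker_mult = {
        st: {gene_idx[g]: fc for g, fc in entries}
        for st, entries in config.marker_spec.items()
    }
    for name, (_n, markers) in config.extra_celltype_spec.items():
        marker_mult[name] = {gene_idx[g]: fc for g, fc in markers}
    de_mult = {
        st: {gene_idx[g]: (2.0 ** l2fc, cond) for g, l2fc, cond in entries}
        for st, entries in config.de_spec.items()
    }
    ds_mult = {
        st: {gene_idx[g]: m for g, m in entries}
        for st, entries in config.ds_spec.items()
    }
    inflamed = config.conditions[1]

    mito_frac_a = config.mito_frac_mean * config.mito_frac_concentration
    mito_frac_b = (1.0 - config.mito_frac_mean) * config.mito_frac_concentration
    mito_frac = rng.beta(mito_frac_a, mito_frac_b, size=n_cells)
    lec_cells = [i for i, r in enumerate(cell_rows) if r["subtype"] in config.subtype_names]
    if config.n_high_mito_cells > 0:
        if config.n_high_mito_cells > len(lec_cells):
            raise ValueError("n_high_mito_cells exceeds the number of LEC cells")
        chosen = rng.choice(lec_cells, size=config.n_high_mito_cells, replace=False)
        mito_frac[chosen] = config.high_mito_frac

    depth = _lognormal(rng, config.depth_mean, config.depth_cv, n_cells)
    batch_factor = {
        b: config.batch_depth_factor**k for k, b in enumerate(config.batch_names)
    }

    mean_s = np.empty((n_cells, n_genes))
    mean_u = np.empty((n_cells, n_genes))
    for i, row in enumerate(cell_rows):
        st, cond = row["subtype"], row["condition"]
        rel = base.copy()
        for gi, fc in marker_mult.get(st, {}).items():
            rel[gi] *= fc
        for gi, (fc, up_cond) in de_mult.get(st, {}).items():
            if cond == up_cond:
                rel[gi] *= fc
        if st == "contaminant":
            rel[cd45_i] = 0.01 * rel.sum()  # ~1% of the library from Cd45
        f = mito_frac[i]
        rel[mito_idx] = f / (1.0 - f) * rel.sum() * mito_weights
        rel /= rel.sum()
        d = depth[i] * batch_factor[row["batch"]]
        mean_s[i] = d * rel
        u = gamma * mean_s[i]
        if cond == inflamed and st in ds_mult:
            for gi, m in ds_mult[st].items():
                u[gi] = u[gi] * m
        mean_u[i] = u

    spliced = _nb_sample(rng, mean_s, config.dispersion).astype(np.int64)
    unspliced = _nb_sample(rng, mean_u, config.dispersion).astype(np.int64)

    obs = pd.DataFrame(cell_rows).set_index("cell")[["condition", "batch"]]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["is_mito"] = [g in set(MITO_GENES) for g in genes]
    var["is_ribo"] = [g in set(RIBO_GENES) for g in genes]
    adata = ad.AnnData(X=spliced, obs=obs, var=var)
    adata.layers["spliced"] = spliced
    adata.layers["unspliced"] = unspliced

    truth = GroundTruth(
        true_subtype=pd.Series(
            [r["subtype"] for r in cell_rows], index=obs.index, name="true_subtype"
        ),
        true_de_genes={
            (st, "up" if l2fc > 0 else "down"): set()
            for st, entries in config.de_spec.items()
            for _, l2fc, _ in entries
        },
        true_ds_genes={st: {g for g, _ in entries} for st, entries in config.ds_spec.items()},
        gamma_true=pd.Series(gamma, index=pd.Index(genes, name="gene"), name="gamma"),
        contaminant_cells={r["cell"] for r in cell_rows if r["subtype"] == "contaminant"},
    )
    for st, entries in config.de_spec.items():
        for g, l2fc, _cond in entries:
            truth.true_de_genes[(st, "up" if l2fc > 0 else "down")].add(g)
    return adata, truth


def write_dataset(adata: ad.AnnData, truth: GroundTruth | None, path: Path) -> None:
    """Write MTX layers + gene/cell TSV sidecars (+ truth TSVs when given)."""
    from . import io as _io  # local import to avoid a cycle

    _io.write_dataset(adata, path, truth=truth)
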