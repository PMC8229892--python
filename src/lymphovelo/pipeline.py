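"""End-to-end orchestration: simulate/ingest -> qc -> cluster -> de -> velocity
-> interactions, with a fixed artifact layout and a run manifest.

Every stage reads only the artifacts of earlier stages from the output
directory and writes its own subdirectory of TSV/MTX files, so a stage can be
rerun in isolation and a rerun with the same seed reproduces every table
byte-identically.  The single global seed fans out to per-stage seeds by
stable hashing of the stage name.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import diffexpr as de
from . import interactions as ia
from . import io as dio
from . import qc as qcm
from . import velocity as vl
from .synthdata import SimConfig, default_config, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "run_stage", "compare_runs", "STAGES"]

STAGES = ("simulate", "qc", "cluster", "de", "velocity", "interactions")

FLOAT_FMT = "%.10g"

DEFAULT_LR_PAIRS = (
    ia.LRPair("Ccl20_Ccr6", ("Ccl20",), ("Ccr6",)),
    ia.LRPair("Fn1_Cd44", ("Fn1",), ("Cd44",)),
    ia.LRPair("Jam3_Itga2b", ("Jam3",), ("Itga2b",)),
)


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "lymphovelo_run"
    seed: int = 0
    sim: SimConfig | None = None  # default: default_config(seed)
    input_path: str | None = None  # pre-existing dataset dir instead of simulation
    qc: qcm.QCParams = field(default_factory=qcm.QCParams)
    clustering: cl.ClusterParams = field(default_factory=cl.ClusterParams)
    de: de.DEParams = field(default_factory=de.DEParams)
    velocity: vl.VelocityParams = field(default_factory=vl.VelocityParams)
    interactions: ia.InteractionParams = field(default_factory=ia.InteractionParams)
    lr_pairs: tuple[ia.LRPair, ...] = DEFAULT_LR_PAIRS
    subtype_rules: tuple[cl.SubtypeRule, ...] = cl.DEFAULT_SUBTYPE_RULES
    count_window_quantiles: tuple[float, float] | None = (0.005, 0.995)
    condition_case: str = "inflamed"
    condition_control: str = "naive"


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(table: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


# --------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.sim if cfg.sim is not None else default_config()
    sim = replace(sim, seed=_stage_seed(cfg.seed, "simulate"))
    adata, truth = generate_dataset(sim)
    dio.write_dataset(adata, out / "data", truth=truth)


def _load_raw(cfg: PipelineConfig, out: Path):
    src = Path(cfg.input_path) if cfg.input_path else out / "data"
    return dio.read_dataset(src)


def _stage_qc(cfg: PipelineConfig, out: Path) -> None:
    adata, truth = _load_raw(cfg, out)
    params = cfg.qc
    if cfg.count_window_quantiles is not None:
        lib = np.asarray(adata.layers["spliced"]).sum(axis=1)
        params = params.with_count_window_from(lib, *cfg.count_window_quantiles)
    filtered, report = qcm.apply_cell_filters(adata, params)
    _write_tsv(report.rename_axis("cell").reset_index(), out / "qc" / "qc_report.tsv")
    (out / "qc" / "summary.json").write_text(
        json.dumps(qcm.qc_summary(report), indent=2, sort_keys=True) + "\n"
    )
    dio.write_dataset(filtered, out / "qc" / "filtered", truth=None)


def _derive_embedding(cfg: PipelineConfig, out: Path):
    """Normalized expression, HVGs, adjusted matrix and PCA of the QC-passed
    cells — recomputed deterministically from the filtered counts so that any
    stage needing the embedding is independent of float round-trips."""
    adata, _ = dio.read_dataset(out / "qc" / "filtered")
    normalized = qcm.lognormalize(adata, cfg.qc.scale_factor)
    hvg = qcm.select_hvg(normalized, min(cfg.qc.hvg_n, normalized.shape[1]))
    adjusted = qcm.regress_out(normalized[hvg])
    if cfg.clustering.batch_key is not None:
        adjusted = cl.center_batches(adjusted, adata.obs[cfg.clustering.batch_key])
    n_pcs = min(cfg.clustering.n_pcs, min(adjusted.shape) - 1)
    pca = cl.embed_pca(adjusted, n_pcs=n_pcs)
    return adata, normalized, hvg, pca


def _stage_cluster(cfg: PipelineConfig, out: Path) -> None:
    adata, normalized, hvg, pca = _derive_embedding(cfg, out)
    labels = cl.snn_cluster(
        pca,
        knn_k=min(cfg.clustering.knn_k, len(pca) - 1),
        resolution=cfg.clustering.resolution,
        seed=_stage_seed(cfg.seed, "cluster"),
        prune=cfg.clustering.snn_prune,
    )
    subtype_of = cl.annotate_subtypes(labels, normalized, cfg.subtype_rules)
    assignments = pd.DataFrame(
        {
            "cell": normalized.index,
            "cluster": labels,
            "subtype": [subtype_of[c] for c in labels],
        }
    )
    _write_tsv(assignments, out / "cluster" / "assignments.tsv")
    _write_tsv(pca.rename_axis("cell").reset_index(), out / "cluster" / "pca.tsv")
    marker_tables = []
    condition = adata.obs["condition"]
    for c in sorted(set(labels.tolist())):
        try:
            marker_tables.append(
                cl.conserved_markers(normalized, labels, condition, c)
            )
        except ValueError:
            continue  # cluster absent in one condition: no conserved markers
    markers = (
        pd.concat(marker_tables, ignore_index=True)
        if marker_tables
        else pd.DataFrame(columns=["gene", "cluster", "p_combined", "min_log2fc"])
    )
    _write_tsv(markers, out / "cluster" / "markers.tsv")


def _subtype_series(out: Path, index) -> pd.Series:
    assignments = pd.read_csv(out / "cluster" / "assignments.tsv", sep="\t").set_index("cell")
    return assignments.loc[index, "subtype"]


def _stage_de(cfg: PipelineConfig, out: Path) -> None:
    adata, _ = dio.read_dataset(out / "qc" / "filtered")
    normalized = qcm.lognormalize(adata, cfg.qc.scale_factor)
    subtypes = _subtype_series(out, normalized.index)
    counts = pd.DataFrame(
        np.asarray(adata.layers["spliced"]), index=normalized.index, columns=normalized.columns
    )
    table = de.de_by_subtype(
        normalized,
        subtypes,
        adata.obs["condition"],
        cfg.de,
        case=cfg.condition_case,
        control=cfg.condition_control,
        counts=counts,
    )
    _write_tsv(table, out / "de" / "de_table.tsv")
    per_subtype = [g for _, g in table.groupby("subtype")]
    names = sorted(table["subtype"].unique().tolist())
    if len(per_subtype) >= 2:
        _write_tsv(de.de_overlap(per_subtype, names), out / "de" / "overlap.tsv")


def _stage_velocity(cfg: PipelineConfig, out: Path) -> None:
    adata, normalized, hvg, pca = _derive_embedding(cfg, out)
    subtypes = _subtype_series(out, normalized.index)
    spliced = pd.DataFrame(
        np.asarray(adata.layers["spliced"]), index=normalized.index, columns=normalized.columns
    )
    unspliced = pd.DataFrame(
        np.asarray(adata.layers["unspliced"]), index=normalized.index, columns=normalized.columns
    )
    genes = vl.filter_velocity_genes(
        spliced, unspliced, subtypes.to_numpy(), cfg.velocity
    )
    S, U = vl.pool_knn(spliced[genes], unspliced[genes], pca, cfg.velocity.k_cells)
    gamma, degenerate = vl.fit_gamma(S, U, cfg.velocity.fit_quantile)
    v = vl.velocity_values(S, U, gamma, cfg.velocity.beta)
    gamma_table = pd.DataFrame(
        {"gene": gamma.index, "gamma": gamma.to_numpy(), "degenerate": degenerate.to_numpy()}
    )
    _write_tsv(gamma_table, out / "velocity" / "gamma.tsv")
    condition = adata.obs["condition"]
    ds_tables = []
    for st in sorted(set(subtypes) - {"unassigned"}):
        try:
            ds_tables.append(
                vl.ds_genes(
                    v, condition, subtypes, st, cfg.velocity, spliced=S,
                    naive=cfg.condition_control, inflamed=cfg.condition_case,
                )
            )
        except ValueError:
            continue
    ds_all = (
        pd.concat(ds_tables, ignore_index=True)
        if ds_tables
        else pd.DataFrame(
            columns=["gene", "subtype", "x_naive", "y_inflamed", "distance", "side", "selected"]
        )
    )
    _write_tsv(ds_all, out / "velocity" / "ds_table.tsv")
    de_path = out / "de" / "de_table.tsv"
    if de_path.exists():
        de_table = pd.read_csv(de_path, sep="\t")
        rows = []
        for st in sorted(ds_all["subtype"].unique().tolist()):
            inter = vl.de_ds_intersect(
                de_table[de_table["subtype"] == st], ds_all[ds_all["subtype"] == st]
            )
            rows.extend({"subtype": st, "gene": g} for g in sorted(inter))
        _write_tsv(
            pd.DataFrame(rows, columns=["subtype", "gene"]),
            out / "velocity" / "de_ds_intersect.tsv",
        )


def _stage_interactions(cfg: PipelineConfig, out: Path) -> None:
    adata, _ = dio.read_dataset(out / "qc" / "filtered")
    normalized = qcm.lognormalize(adata, cfg.qc.scale_factor)
    subtypes = _subtype_series(out, normalized.index)
    pairs = list(cfg.lr_pairs)
    records = ia.permutation_test(
        normalized,
        subtypes,
        pairs,
        n_perm=cfg.interactions.n_perm,
        threshold=cfg.interactions.threshold,
        alpha=cfg.interactions.alpha,
        seed=_stage_seed(cfg.seed, "interactions"),
    )
    de_path = out / "de" / "de_table.tsv"
    if de_path.exists():
        records = ia.intersect_with_de(records, pairs, pd.read_csv(de_path, sep="\t"))
    _write_tsv(records, out / "interactions" / "records.tsv")
    counts, log_counts = ia.interaction_counts(records)
    _write_tsv(counts.rename_axis("sender").reset_index(), out / "interactions" / "counts.tsv")
    _write_tsv(
        log_counts.rename_axis("sender").reset_index(),
        out / "interactions" / "counts_log2.tsv",
    )


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "de": _stage_de,
    "velocity": _stage_velocity,
    "interactions": _stage_interactions,
}


def run_stage(cfg: PipelineConfig, stage: str) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _STAGE_FN[stage](cfg, out)


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the stage sequence, writing artifacts and a manifest.json.

    The manifest records, per stage, the wall time and a sha256 of every file
    the stage wrote; it is written even when a stage fails (with the failing
    stage and cause recorded), and the exception is re-raised.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.input_path is not None:
        stages = tuple(s for s in stages if s != "simulate")
    manifest: dict = {"seed": cfg.seed, "stages": {}, "versions": _versions()}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            _STAGE_FN[stage](cfg, out)
            stage_dir = out / ("data" if stage == "simulate" else stage)
            artifacts = {
                str(p.relative_to(out)): _sha256(p)
                for p in sorted(stage_dir.rglob("*"))
                if p.is_file()
            }
            manifest["stages"][stage] = {
                "wall_time_s": round(time.perf_counter() - t0, 3),
                "artifacts": artifacts,
            }
    except Exception as exc:  # manifest survives stage failure
        manifest["error"] = {"stage": stage, "cause": repr(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _versions() -> dict[str, str]:
    from importlib.metadata import version

    from . import __version__

    return {
        "lymphovelo": __version__,
        **{pkg: version(pkg) for pkg in ("numpy", "pandas", "scipy", "anndata", "scikit-learn")},
    }


def compare_runs(de_a: pd.DataFrame, de_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-study DE overlap: per subtype and direction, the fraction of run
    A's significant genes also significant (same direction) in run B."""
    subtypes = sorted(set(de_a["subtype"].unique()))
    missing = [st for st in subtypes if st not in set(de_b["subtype"].unique())]
    if missing:
        raise ValueError(f"subtype(s) missing in second run: {missing}")
    rows = []
    for st in subtypes:
        for d in ("up", "down"):
            a = de.significant_genes(de_a, st, d)
            b = de.significant_genes(de_b, st, d)
            rows.append(
                {
                    "subtype": st,
                    "direction": d,
                    "n_a": len(a),
                    "n_b": len(b),
                    "n_shared": len(a & b),
                    "overlap_frac": len(a & b) / len(a) if a else np.nan,
                }
            )
    return pd.DataFrame(rows)
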