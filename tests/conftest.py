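import numpy as np
import pytest

from lymphovelo import cluster, qc, synthdata


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 3 subtypes x 2 conditions x 60 cells with
    planted markers, DE, DS effects, contaminants and high-mito cells."""
    cfg = synthdata.default_config(seed=1)
    adata, truth = synthdata.generate_dataset(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def qc_bundle(default_dataset):
    """QC-passed cells with normalized expression, embedding and true labels."""
    _, adata, truth = default_dataset
    filtered, report = qc.apply_cell_filters(adata, qc.QCParams())
    normalized = qc.lognormalize(filtered)
    hvg = qc.select_hvg(normalized, 1000)
    adjusted = qc.regress_out(normalized[hvg])
    pca = cluster.embed_pca(adjusted, n_pcs=20)
    true_subtype = truth.true_subtype.loc[normalized.index]
    return {
        "filtered": filtered,
        "report": report,
        "normalized": normalized,
        "hvg": hvg,
        "pca": pca,
        "condition": filtered.obs["condition"],
        "true_subtype": true_subtype,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def marker_only_dataset():
    """Planted 3-subtype partition with no condition-wise effects."""
    cfg = synthdata.default_config(seed=2, de_spec={}, ds_spec={})
    adata, truth = synthdata.generate_dataset(cfg)
    return cfg, adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
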