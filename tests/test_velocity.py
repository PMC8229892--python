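"""Velocity contracts: gene filtering, kNN pooling and the velocity formula
against brute-force oracles; gamma recovery from steady-state data; the
differentially-speeded statistic's sensitivity and specificity; residual
diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from lymphovelo import cluster, qc
from lymphovelo.synthdata import default_config, generate_dataset
from lymphovelo.velocity import (
    VelocityParams,
    de_ds_intersect,
    ds_genes,
    filter_velocity_genes,
    fit_gamma,
    perpendicular_distance,
    pool_knn,
    unspliced_residuals,
    velocity_values,
)


def _frames(rng, n_cells=20, n_genes=15, scale=20.0):
    s = pd.DataFrame(rng.poisson(scale, size=(n_cells, n_genes)).astype(float),
                     columns=[f"g{i}" for i in range(n_genes)])
    u = pd.DataFrame(rng.poisson(scale / 3, size=(n_cells, n_genes)).astype(float),
                     columns=s.columns)
    return s, u


class TestGeneFilter:
    def test_threshold_examples(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        s = pd.DataFrame({"keep": [6, 6, 0, 0, 0, 0], "low_s": [4.9, 4.9, 0, 0, 0, 0]})
        u = pd.DataFrame({"keep": [1.5, 1.5, 0, 0, 0, 0], "low_s": [9, 9, 9, 9, 9, 9]})
        kept = filter_velocity_genes(s, u, labels)
        assert kept == ["keep"]  # max spliced cluster mean 4.9 drops low_s

    def test_matches_groupby_oracle(self, rng):
        s, u = _frames(rng, scale=4.0)
        labels = rng.integers(0, 3, size=len(s))
        kept = set(filter_velocity_genes(s, u, labels,
                                         VelocityParams(min_max_cluster_avg_spliced=4,
                                                        min_max_cluster_avg_unspliced=1)))
        expected = set()
        for g in s.columns:
            smax = max(s.loc[labels == c, g].mean() for c in set(labels.tolist()))
            umax = max(u.loc[labels == c, g].mean() for c in set(labels.tolist()))
            if smax >= 4 and umax >= 1:
                expected.add(g)
        assert kept == expected

    def test_protein_coding_intersection(self, rng):
        s, u = _frames(rng)
        labels = np.zeros(len(s), dtype=int)
        kept = filter_velocity_genes(s, u, labels, protein_coding={"g0", "g1"})
        assert set(kept) <= {"g0", "g1"}

    def test_empty_result_raises(self, rng):
        s, u = _frames(rng, scale=0.1)
        with pytest.raises(ValueError, match="no gene"):
            filter_velocity_genes(s, u, np.zeros(len(s), dtype=int))


class TestPooling:
    def test_identity_pooling(self, rng):
        s, u = _frames(rng)
        ps, pu = pool_knn(s, u, rng.normal(size=(len(s), 2)), k_cells=0)
        tot = s.sum(axis=1)
        expected = s.div(tot, axis=0) * np.median(tot)
        assert np.allclose(ps, expected, atol=1e-12)

    def test_identical_cells_proportional_profile(self):
        s = pd.DataFrame([[10, 20, 30]] * 3, columns=list("abc")).astype(float)
        u = s / 2
        emb = np.zeros((3, 2))
        ps, pu = pool_knn(s, u, emb, k_cells=2)
        ratio = ps.iloc[0] / s.iloc[0]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_matches_brute_force_neighbor_sums(self, rng):
        s, u = _frames(rng, n_cells=10)
        emb = rng.normal(size=(10, 3))
        k = 3
        ps, _ = pool_knn(s, u, emb, k_cells=k)
        # brute-force kNN (self + k nearest by Euclidean distance)
        d = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        pooled = np.empty_like(s.to_numpy())
        for i in range(10):
            nb = np.argsort(d[i], kind="stable")[: k + 1]
            pooled[i] = s.to_numpy()[nb].sum(axis=0)
        tot = pooled.sum(axis=1)
        expected = pooled / tot[:, None] * np.median(tot)
        assert np.allclose(ps.to_numpy(), expected, atol=1e-12)

    def test_k_too_large(self, rng):
        s, u = _frames(rng, n_cells=5)
        with pytest.raises(ValueError):
            pool_knn(s, u, rng.normal(size=(5, 2)), k_cells=5)


class TestFitGamma:
    def test_noiseless_steady_state(self):
        s = pd.DataFrame({"g": np.linspace(1, 50, 20)})
        gamma, deg = fit_gamma(s, 2.0 * s)
        assert gamma["g"] == pytest.approx(2.0, abs=1e-12)
        assert not deg["g"]

    def test_orthogonal_gives_zero(self):
        s = pd.DataFrame({"g": [1.0, -1.0, 2.0, -2.0]})
        u = pd.DataFrame({"g": [1.0, 1.0, -0.5, -0.5]})  # sum(U*S) = 0
        gamma, _ = fit_gamma(s, u)
        assert gamma["g"] == 0.0

    def test_all_zero_s_flagged(self):
        s = pd.DataFrame({"g": np.zeros(6)})
        u = pd.DataFrame({"g": np.ones(6)})
        gamma, deg = fit_gamma(s, u)
        assert gamma["g"] == 0.0
        assert bool(deg["g"])

    def test_quantile_selects_extremes(self):
        s_vals = np.arange(1.0, 21.0)
        u_vals = 0.5 * s_vals
        u_vals[8:12] = 100.0  # corrupt the middle: q=0.2 should ignore it
        gamma_all, _ = fit_gamma(pd.DataFrame({"g": s_vals}), pd.DataFrame({"g": u_vals}), 0.5)
        gamma_ext, _ = fit_gamma(pd.DataFrame({"g": s_vals}), pd.DataFrame({"g": u_vals}), 0.2)
        assert gamma_ext["g"] == pytest.approx(0.5, abs=1e-12)
        assert gamma_all["g"] > 0.6

    def test_recovery_from_generator(self):
        """Median relative gamma error <= 15% at 300 cells, decreasing in n."""
        errs = {}
        for n in (75, 150, 300):
            cfg = default_config(
                seed=11, subtype_names=("uniform",), marker_spec={}, de_spec={},
                ds_spec={}, gamma_true={}, gamma_range=(0.2, 2.0),
                n_cells_per_subtype_per_condition=n // 2,
                n_contaminant_cells=0, n_high_mito_cells=0,
            )
            adata, truth = generate_dataset(cfg)
            norm = qc.lognormalize(adata)
            adjusted = qc.regress_out(norm[qc.select_hvg(norm, 1000)])
            pca = cluster.embed_pca(adjusted, n_pcs=20)
            s = pd.DataFrame(adata.layers["spliced"], index=norm.index, columns=norm.columns)
            u = pd.DataFrame(adata.layers["unspliced"], index=norm.index, columns=norm.columns)
            genes = filter_velocity_genes(s, u, np.zeros(len(s), dtype=int))
            S, U = pool_knn(s[genes], u[genes], pca, 5)
            gamma, _ = fit_gamma(S, U, 0.5)
            rel = np.abs(gamma - truth.gamma_true[genes]) / truth.gamma_true[genes]
            errs[n] = float(np.median(rel))
        assert errs[300] <= 0.15
        assert errs[300] < errs[150] < errs[75]


class TestVelocityValues:
    def test_arithmetic_example(self):
        s = pd.DataFrame({"g": [4.0]})
        u = pd.DataFrame({"g": [3.0]})
        v = velocity_values(s, u, pd.Series({"g": 0.5}), beta=1.0)
        assert v.iloc[0, 0] == 1.0

    def test_gamma_equals_ratio_gives_zero(self, rng):
        s, _ = _frames(rng)
        s = s + 1.0
        u = 0.7 * s
        v = velocity_values(s, u, pd.Series(0.7, index=s.columns))
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        s, u = _frames(rng, n_cells=20, n_genes=15)
        gamma = pd.Series(rng.uniform(0.1, 2.0, 15), index=s.columns)
        v = velocity_values(s, u, gamma, beta=1.3)
        expected = 1.3 * u.to_numpy() - s.to_numpy() * gamma.to_numpy()[None, :]
        assert np.max(np.abs(v.to_numpy() - expected)) < 1e-12

    def test_shape_mismatch(self, rng):
        s, u = _frames(rng)
        with pytest.raises(ValueError):
            velocity_values(s, u.iloc[:5], pd.Series(1.0, index=s.columns))


class TestDSGenes:
    def _v(self, x, y, n=10):
        """Velocity matrix with per-condition means exactly (x, y)."""
        v = pd.DataFrame({"g": [x] * n + [y] * n})
        cond = pd.Series(["naive"] * n + ["inflamed"] * n, index=v.index)
        labels = np.array(["s"] * 2 * n)
        return v, cond, labels

    def test_hand_computed_distance(self):
        v, cond, labels = self._v(0.5, 0.8)
        tab = ds_genes(v, cond, labels, "s")
        assert tab.loc[0, "distance"] == pytest.approx(0.3 / math.sqrt(2), abs=1e-12)
        assert bool(tab.loc[0, "selected"])
        assert tab.loc[0, "side"] == "above"

    def test_identity_line_nothing_selected(self, rng):
        n = 12
        vals = rng.normal(size=n)
        v = pd.DataFrame({f"g{i}": np.r_[vals, vals] for i in range(4)})
        cond = pd.Series(["naive"] * n + ["inflamed"] * n, index=v.index)
        tab = ds_genes(v, cond, np.array(["s"] * 2 * n), "s")
        assert not tab["selected"].any()

    def test_distance_matches_rotation_oracle(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        # rotate by -45 degrees: the identity line maps onto the first axis and
        # the distance is the absolute second coordinate
        rot = np.array([[math.cos(-math.pi / 4), -math.sin(-math.pi / 4)],
                        [math.sin(-math.pi / 4), math.cos(-math.pi / 4)]])
        second = (rot @ np.vstack([x, y]))[1]
        assert np.allclose(perpendicular_distance(x, y), np.abs(second), atol=1e-12)

    def test_planted_recovery_and_specificity(self, qc_bundle):
        """Planted unspliced x3 genes recovered (sens >= 0.8); null genes rarely
        exceed the 0.1 distance threshold (<= 5%)."""
        truth = qc_bundle["truth"]
        norm = qc_bundle["normalized"]
        filtered = qc_bundle["filtered"]
        s = pd.DataFrame(np.asarray(filtered.layers["spliced"]), index=norm.index,
                         columns=norm.columns)
        u = pd.DataFrame(np.asarray(filtered.layers["unspliced"]), index=norm.index,
                         columns=norm.columns)
        labels = qc_bundle["true_subtype"]
        genes = filter_velocity_genes(s, u, labels.to_numpy())
        S, U = pool_knn(s[genes], u[genes], qc_bundle["pca"], 5)
        gamma, _ = fit_gamma(S, U, 0.5)
        v = velocity_values(S, U, gamma)
        for st in ("floor", "ceiling", "medullary"):
            tab = ds_genes(v, qc_bundle["condition"], labels, st, spliced=S)
            selected = set(tab.loc[tab["selected"], "gene"])
            planted = truth.true_ds_genes[st] & set(genes)
            assert len(planted) >= 8
            assert len(selected & planted) / len(planted) >= 0.8
            null = set(genes) - truth.true_ds_genes[st]
            assert len(selected & null) / len(null) <= 0.05

    def test_missing_condition_raises(self):
        v = pd.DataFrame({"g": [1.0, 2.0]})
        cond = pd.Series(["naive", "naive"], index=v.index)
        with pytest.raises(ValueError):
            ds_genes(v, cond, np.array(["s", "s"]), "s")


class TestResiduals:
    def test_noiseless_steady_state_zero(self):
        s = pd.Series(np.linspace(1, 10, 8))
        cond = pd.Series(["naive"] * 4 + ["inflamed"] * 4)
        resid, means = unspliced_residuals(s, 0.5 * s, 0.5, cond)
        assert np.allclose(resid, 0.0, atol=1e-12)
        assert means == {"inflamed": 0.0, "naive": 0.0}

    def test_planted_excess_raises_inflamed_mean(self, rng):
        s = pd.Series(rng.poisson(20, 40).astype(float))
        cond = pd.Series(["naive"] * 20 + ["inflamed"] * 20)
        u = 0.5 * s
        u.iloc[20:] *= 3.0
        _, means = unspliced_residuals(s, u, 0.5, cond)
        assert means["inflamed"] > means["naive"]

    def test_equals_velocity_at_beta_one(self, rng):
        s, u = _frames(rng, n_genes=1)
        cond = pd.Series(["naive"] * 10 + ["inflamed"] * 10, index=s.index)
        resid, _ = unspliced_residuals(s["g0"], u["g0"], 0.4, cond)
        v = velocity_values(s[["g0"]], u[["g0"]], pd.Series({"g0": 0.4}), beta=1.0)
        assert np.allclose(resid, v["g0"], atol=1e-15)


class TestDeDsIntersect:
    @staticmethod
    def _de(genes):
        return pd.DataFrame({"gene": genes, "significant": True})

    @staticmethod
    def _ds(genes):
        return pd.DataFrame({"gene": genes, "selected": True})

    def test_disjoint_empty(self):
        assert de_ds_intersect(self._de(["a"]), self._ds(["b"])) == set()

    def test_shared_gene_present_and_subset(self):
        de = self._de(["a", "b", "c"])
        ds = self._ds(["b", "c", "d"])
        got = de_ds_intersect(de, ds)
        assert got == {"b", "c"}
        assert got <= set(de["gene"]) and got <= set(ds["gene"])
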