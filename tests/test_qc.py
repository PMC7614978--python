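"""QC chain: filters, doublet-cluster rule, normalization, HVGs, markers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dropmics import (
    SimulationConfig,
    filter_cells_and_genes,
    generate_multiomic_dataset,
    normalize_lognorm,
    partition_metrics,
    rank_marker_genes,
    remove_doublet_clusters,
    select_hvgs,
    sweep_partition_metrics,
)
from conftest import make_adata


def _qc_fixture():
    """6 cells x 600 genes with hand-planted QC outcomes."""
    rng = np.random.default_rng(0)
    n_genes = 600
    X = np.zeros((6, n_genes))
    # cell 0: 1999 counts over 500 genes -> removed (low counts)
    X[0, :500] = 3
    X[0, 0] = 3 + (1999 - 1500)
    # cell 1: exactly 2000 counts, 200 genes, 20% mito -> retained (strict)
    X[1, :200] = 10
    # cells 2-5: clearly passing
    for i in range(2, 6):
        X[i, :550] = rng.integers(4, 10, size=550)
    # gene 590: expressed in exactly 2 surviving cells -> removed
    X[2, 590] = 1
    X[3, 590] = 1
    # gene 591: expressed in exactly 3 surviving cells -> retained
    X[2:5, 591] = 1
    mito = [0.05, 0.20, 0.01, 0.01, 0.01, 0.01]
    return make_adata(X, pct_mito=mito)


class TestCellGeneFilters:
    def test_hand_planted_outcomes(self):
        adata = _qc_fixture()
        out, report = filter_cells_and_genes(adata)
        assert "c0" not in out.obs_names          # 1999 counts < 2000
        assert "c1" in out.obs_names              # boundary cell retained
        assert "g590" not in out.var_names        # 2 expressing cells
        assert "g591" in out.var_names            # 3 expressing cells
        assert report.n_cells_out == 5
        assert report.removed_by_filter["low_counts"] == 1

    def test_missing_mito_raises(self):
        adata = _qc_fixture()
        del adata.obs["pct_mito"]
        with pytest.raises(KeyError):
            filter_cells_and_genes(adata)

    @given(st.integers(min_value=0, max_value=4000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_filter_monotone_in_min_counts(self, min_counts):
        adata = _qc_fixture()
        lo, _ = filter_cells_and_genes(adata, min_counts=min_counts, min_genes=0)
        hi, _ = filter_cells_and_genes(adata, min_counts=min_counts + 500, min_genes=0)
        assert hi.n_obs <= lo.n_obs
        assert set(hi.obs_names) <= set(lo.obs_names)


def _cluster_fixture(medians, lane="L0", cells_per_cluster=3, shift=0.0):
    scores, clusters = [], []
    for i, m in enumerate(medians):
        scores += [m + shift] * cells_per_cluster
        clusters += [f"cl{i}"] * cells_per_cluster
    n = len(scores)
    return make_adata(
        np.ones((n, 5)),
        doublet_score=scores,
        cluster_id=clusters,
        lane_id=[lane] * n,
    )


class TestDoubletClusterRule:
    def test_hand_computed_threshold(self):
        # medians {0.05, 0.06, 0.50}: threshold 0.06 + 1.48*0.01 = 0.0748
        adata = _cluster_fixture([0.05, 0.06, 0.50])
        out, report = remove_doublet_clusters(adata)
        info = report.removed_clusters["L0"]
        assert info["threshold"] == pytest.approx(0.0748)
        assert info["removed_clusters"] == ["cl2"]
        assert set(out.obs["cluster_id"]) == {"cl0", "cl1"}

    def test_equal_medians_remove_nothing(self):
        adata = _cluster_fixture([0.07, 0.07, 0.07, 0.07])
        out, report = remove_doublet_clusters(adata)
        assert out.n_obs == adata.n_obs
        assert report.removed_clusters["L0"]["removed_clusters"] == []

    def test_shift_equivariance(self):
        base = _cluster_fixture([0.03, 0.05, 0.06, 0.4])
        shifted = _cluster_fixture([0.03, 0.05, 0.06, 0.4], shift=0.17)
        _, r1 = remove_doublet_clusters(base)
        _, r2 = remove_doublet_clusters(shifted)
        assert (
            r1.removed_clusters["L0"]["removed_clusters"]
            == r2.removed_clusters["L0"]["removed_clusters"]
        )

    def test_single_cluster_lane_untouched(self):
        adata = _cluster_fixture([0.9])
        out, report = remove_doublet_clusters(adata)
        assert out.n_obs == adata.n_obs
        assert any("single cluster" in n for n in report.notes)

    def test_planted_doublet_cluster_removed(self):
        cfg = SimulationConfig(n_cells=1500, n_genes=100, n_samples=2,
                               empty_droplet_count=0, seed=17)
        rna, _, truth = generate_multiomic_dataset(cfg)
        out, report = remove_doublet_clusters(rna)
        removed = {
            c for info in report.removed_clusters.values()
            for c in info["removed_clusters"]
        }
        assert removed == {"doublet"}


class TestNormalize:
    def test_hand_computed_values(self):
        adata = make_adata(np.array([[1.0, 1.0, 2.0]]), pct_mito=[0.0])
        normalize_lognorm(adata)
        got = adata.layers["lognorm"].toarray()[0]
        assert np.allclose(got, np.log1p([2500, 2500, 5000]), atol=1e-10)
        assert got[0] == pytest.approx(7.8244, abs=1e-3)
        assert got[2] == pytest.approx(8.5174, abs=1e-3)

    def test_row_sums_and_zero_gene(self, small_multiomic):
        rna = small_multiomic[0].copy()
        normalize_lognorm(rna)
        pre_log = np.expm1(rna.layers["lognorm"].toarray())
        assert np.allclose(pre_log.sum(axis=1), 1e4, rtol=1e-9)
        zero_genes = np.asarray((rna.X > 0).sum(axis=0)).ravel() == 0
        if zero_genes.any():
            assert np.all(pre_log[:, zero_genes] == 0)

    def test_relative_proportions_recovered(self):
        X = np.array([[2.0, 6.0, 12.0], [5.0, 0.0, 5.0]])
        adata = make_adata(X)
        normalize_lognorm(adata)
        back = np.expm1(adata.layers["lognorm"].toarray())
        back = back / back.sum(axis=1, keepdims=True)
        assert np.allclose(back, X / X.sum(axis=1, keepdims=True), atol=1e-12)

    def test_zero_count_cell_raises(self):
        adata = make_adata(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="zero total"):
            normalize_lognorm(adata)


class TestHVGs:
    @staticmethod
    def _bimodal_fixture(seed):
        # 10 bimodal (high-variance) genes interleaved, by mean, among
        # 300 low-noise genes so they share bins with null peers
        rng = np.random.default_rng(seed)
        n, g_null, g_hv = 1000, 300, 10
        mu = np.concatenate(
            [rng.uniform(0.2, 1.6, g_null), rng.uniform(0.3, 0.8, g_hv)]
        )
        layer = rng.normal(mu, 0.2, size=(n, g_null + g_hv))
        flip = rng.random(n) < 0.5
        hv_cols = np.arange(g_null, g_null + g_hv)
        layer[np.ix_(flip, hv_cols)] += 0.8
        layer[np.ix_(~flip, hv_cols)] -= 0.8
        layer = np.clip(layer, 0, None)
        adata = make_adata(np.ones_like(layer))
        adata.layers["lognorm"] = layer
        return adata, {f"g{j}" for j in hv_cols}

    def test_planted_high_variance_genes_recovered(self):
        adata, planted = self._bimodal_fixture(13)
        top = set(select_hvgs(adata, n_top=30))
        assert planted <= top

    def test_scanpy_agrees_on_high_variance_ranking(self):
        # independent oracle: scanpy's seurat-flavor dispersion ranking
        # recovers the same planted genes
        import scanpy as sc
        import anndata as ad

        adata, planted = self._bimodal_fixture(99)
        ours = set(select_hvgs(adata, n_top=30))
        ref = ad.AnnData(X=np.asarray(adata.layers["lognorm"]).copy(),
                         var=adata.var.copy())
        sc.pp.highly_variable_genes(ref, flavor="seurat", n_top_genes=30)
        theirs = set(ref.var_names[ref.var["highly_variable"]])
        assert planted <= ours
        assert planted <= theirs

    def test_mean_window_and_constant_gene(self):
        rng = np.random.default_rng(1)
        n = 400
        layer = np.log1p(rng.gamma(2.0, 1.0, size=(n, 60)))
        layer[:, 1] = 0.0005  # mean below min_mean: excluded despite 0 variance quirk
        layer[:, 2] = np.log1p(5.0)  # constant nonzero gene, zero dispersion
        adata = make_adata(np.ones((n, 60)))
        adata.layers["lognorm"] = layer
        hv = select_hvgs(adata, n_top=30)
        assert "g1" not in hv
        assert "g2" not in hv

    def test_warns_when_too_few_eligible(self):
        adata = make_adata(np.random.default_rng(2).poisson(3, (100, 20)).astype(float))
        normalize_lognorm(adata)
        with pytest.warns(UserWarning, match="eligible"):
            hv = select_hvgs(adata, n_top=500)
        assert len(hv) <= 20


class TestMarkerRanking:
    def test_planted_marker_recovered(self, lognormed_rna):
        rna, truth = lognormed_rna
        table = rank_marker_genes(rna, groupby="state")
        for state, genes in truth.marker_genes.items():
            rows = table[(table["group"] == state) & (table["logFC"] > 0)]
            found = set(rows[rows["p_adj"] < 0.05]["gene"])
            assert len(found & set(genes)) >= len(genes) - 1

    def test_low_expression_fraction_not_tested(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(5, (100, 30)).astype(float)
        X[:, 0] = 0.0
        X[rng.choice(50, 10, replace=False), 0] = 50.0  # 20% of group 'a'
        adata = make_adata(X, group=["a"] * 50 + ["b"] * 50)
        normalize_lognorm(adata)
        table = rank_marker_genes(adata, groupby="group")
        assert "g0" not in set(table[table["group"] == "a"]["gene"])

    def test_null_groups_yield_no_markers(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(5, (300, 80)).astype(float)
        adata = make_adata(X, group=rng.choice(["a", "b"], 300))
        normalize_lognorm(adata)
        table = rank_marker_genes(adata, groupby="group")
        assert (table["p_adj"] < 0.05).sum() == 0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(8, (120, 25)).astype(float)
        adata = make_adata(X, group=["a"] * 60 + ["b"] * 60)
        normalize_lognorm(adata)
        t1 = rank_marker_genes(adata, groupby="group", logfc_cutoff=0.0)
        adata.layers["lognorm"] = np.asarray(adata.layers["lognorm"].todense()) ** 3
        t2 = rank_marker_genes(adata, groupby="group", logfc_cutoff=0.0)
        merged = t1.merge(t2, on=["group", "gene"], suffixes=("_1", "_2"))
        assert np.allclose(merged["pvalue_1"], merged["pvalue_2"], atol=1e-12)

    def test_tiny_group_raises(self):
        adata = make_adata(np.ones((3, 5)), group=["a", "b", "b"])
        normalize_lognorm(adata)
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_marker_genes(adata, groupby="group")


class TestPartitionMetrics:
    def test_identity_and_permutation(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 4, 200)
        renamed = (labels + 1) % 4
        m = partition_metrics(labels, labels)
        assert m.ami == pytest.approx(1.0)
        assert m.ari == pytest.approx(1.0)
        m2 = partition_metrics(labels, renamed)
        assert m2.ami == pytest.approx(1.0)
        assert m2.ari == pytest.approx(1.0)

    def test_random_labels_have_near_zero_ari(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 5, 5000)
        b = rng.integers(0, 5, 5000)
        m = partition_metrics(a, b)
        assert abs(m.ari) < 0.02

    def test_wss_hand_computed_and_single_cluster_sentinel(self):
        emb = np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]])
        labels = np.array([0, 0, 1, 1])
        m = partition_metrics(labels, labels, emb)
        assert m.wss == pytest.approx(4.0)  # each pair: 2 * (1^2)
        single = partition_metrics(labels, np.zeros(4), emb)
        assert np.isnan(single.silhouette)

    def test_sweep_helper(self):
        labels = np.array([0, 0, 1, 1])
        df = sweep_partition_metrics(labels, {"k5": labels, "k10": [0, 1, 0, 1]})
        assert list(df["partition"]) == ["k5", "k10"]
        assert df.loc[0, "ari"] == pytest.approx(1.0)
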