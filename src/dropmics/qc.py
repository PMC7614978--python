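"""Droplet RNA quality control, normalization and marker statistics.

Implements the fixed QC chain for UMI count matrices: strict cell/gene
threshold filters, the per-lane doublet-cluster purge based on the
median + 1.48 * MAD rule over cluster-level doublet scores, total-count
normalization with log transform, dispersion-based highly-variable-gene
selection, one-vs-rest Wilcoxon marker testing with an expression-fraction
gate, and partition benchmarking metrics (AMI/ARI/silhouette/WSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCReport",
    "filter_cells_and_genes",
    "remove_doublet_clusters",
    "normalize_lognorm",
    "select_hvgs",
    "rank_marker_genes",
    "partition_metrics",
    "sweep_partition_metrics",
    "PartitionMetrics",
]


@dataclass
class QCReport:
    """Cell/gene tallies of one QC step, serializable as a plain dict."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_by_filter: dict[str, int] = field(default_factory=dict)
    removed_clusters: dict[str, dict] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "removed_by_filter": self.removed_by_filter,
            "removed_clusters": self.removed_clusters,
            "notes": self.notes,
        }


def _row_sums(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel()


def filter_cells_and_genes(
    adata: ad.AnnData,
    min_counts: int = 2000,
    min_genes: int = 200,
    max_mito: float = 0.20,
    min_cells_per_gene: int = 3,
) -> tuple[ad.AnnData, QCReport]:
    """Strict threshold filters: cells with fewer than ``min_counts`` total
    UMIs, fewer than ``min_genes`` detected genes, or more than
    ``max_mito`` mitochondrial fraction are removed; then genes expressed
    in fewer than ``min_cells_per_gene`` of the remaining cells are
    removed.  Boundary values are retained (the inequalities are strict).
    """
    if "pct_mito" not in adata.obs:
        raise KeyError("filter_cells_and_genes requires obs['pct_mito']")
    X = sparse.csr_matrix(adata.X)
    total = _row_sums(X)
    n_genes_per_cell = X.getnnz(axis=1)
    mito = adata.obs["pct_mito"].to_numpy(dtype=float)

    low_counts = total < min_counts
    low_genes = n_genes_per_cell < min_genes
    high_mito = mito > max_mito
    keep_cells = ~(low_counts | low_genes | high_mito)

    sub = adata[keep_cells].copy()
    cells_per_gene = sparse.csr_matrix(sub.X).getnnz(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = sub[:, keep_genes].copy()
    out.var["n_cells_expressing"] = cells_per_gene[keep_genes]

    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=adata.n_vars,
        n_genes_out=out.n_vars,
        removed_by_filter={
            "low_counts": int(low_counts.sum()),
            "low_genes": int(low_genes.sum()),
            "high_mito": int(high_mito.sum()),
            "cells_removed": int((~keep_cells).sum()),
            "genes_removed": int((~keep_genes).sum()),
        },
    )
    return out, report


def _unscaled_mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def remove_doublet_clusters(
    adata: ad.AnnData,
    cluster_key: str = "cluster_id",
    lane_key: str = "lane_id",
    score_key: str = "doublet_score",
    mad_factor: float = 1.48,
) -> tuple[ad.AnnData, QCReport]:
    """Per sequencing lane, drop clusters whose median doublet score
    strictly exceeds median(cluster medians) + ``mad_factor`` * MAD
    (MAD unscaled).  A lane with a single cluster is never touched (the
    rule is undefined there); such lanes are flagged in the report.
    """
    for key in (cluster_key, lane_key, score_key):
        if key not in adata.obs:
            raise KeyError(f"remove_doublet_clusters requires obs[{key!r}]")
    obs = adata.obs
    drop = np.zeros(adata.n_obs, dtype=bool)
    removed: dict[str, dict] = {}
    notes: list[str] = []
    for lane, idx in obs.groupby(lane_key, observed=True).indices.items():
        scores = obs[score_key].to_numpy(dtype=float)[idx]
        clusters = np.asarray(obs[cluster_key])[idx]
        med = pd.Series(scores).groupby(clusters).median()
        if len(med) < 2:
            notes.append(f"lane {lane}: single cluster, doublet rule not applied")
            continue
        centre = float(np.median(med.to_numpy()))
        mad = _unscaled_mad(med.to_numpy())
        threshold = centre + mad_factor * mad
        bad = med.index[med.to_numpy() > threshold]
        removed[str(lane)] = {
            "threshold": threshold,
            "median_of_medians": centre,
            "mad": mad,
            "removed_clusters": [str(c) for c in bad],
        }
        if len(bad):
            drop[idx[np.isin(clusters, bad)]] = True
    out = adata[~drop].copy()
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=adata.n_vars,
        n_genes_out=out.n_vars,
        removed_by_filter={"doublet_cluster_cells": int(drop.sum())},
        removed_clusters=removed,
        notes=notes,
    )
    return out, report


def normalize_lognorm(
    adata: ad.AnnData, target_sum: float = 1e4, layer: str = "lognorm"
) -> ad.AnnData:
    """Scale every cell to ``target_sum`` total counts, then apply
    ln(1 + x); stored as a layer, raw counts untouched."""
    X = sparse.csr_matrix(adata.X, dtype=np.float64)
    total = _row_sums(X)
    if np.any(total == 0):
        raise ValueError(
            "normalize_lognorm found cells with zero total counts; "
            "filter cells first"
        )
    scaled = sparse.diags(target_sum / total) @ X
    scaled.data = np.log1p(scaled.data)
    adata.layers[layer] = scaled.tocsr()
    return adata


def _layer_dense(adata: ad.AnnData, layer: str) -> np.ndarray:
    if layer not in adata.layers:
        raise KeyError(f"layer {layer!r} missing; run normalize_lognorm first")
    M = adata.layers[layer]
    return M.toarray() if sparse.issparse(M) else np.asarray(M)


def select_hvgs(
    adata: ad.AnnData,
    n_top: int,
    min_mean: float = 0.001,
    max_mean: float = 10.0,
    n_bins: int = 20,
    layer: str = "lognorm",
) -> list[str]:
    """Dispersion-based highly-variable-gene selection.

    Means and dispersions (var/mean) are computed on the linearized
    log-normalized layer (expm1), genes are cut into ``n_bins``
    equal-frequency mean bins, dispersions are z-scored within bins, and
    genes with mean strictly inside (min_mean, max_mean) are ranked by
    the normalized dispersion; the top ``n_top`` names are returned.
    """
    L = np.expm1(_layer_dense(adata, layer))
    mean = L.mean(axis=0)
    var = L.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = pd.Series(mean).rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(mean)), labels=False, duplicates="drop")
    disp_norm = np.zeros_like(disp)
    for b in np.unique(bins):
        members = bins == b
        mu = disp[members].mean()
        sd = disp[members].std(ddof=1) if members.sum() > 1 else 0.0
        disp_norm[members] = (disp[members] - mu) / sd if sd > 0 else 0.0
    eligible = (mean > min_mean) & (mean < max_mean)
    idx = np.flatnonzero(eligible)
    if n_top > idx.size:
        warnings.warn(
            f"requested {n_top} HVGs but only {idx.size} genes are eligible; "
            "returning all eligible genes"
        )
        n_top = idx.size
    ranked = idx[np.argsort(-disp_norm[idx], kind="stable")][:n_top]
    return list(adata.var_names[np.sort(ranked)])


def rank_marker_genes(
    adata: ad.AnnData,
    groupby: str,
    min_frac_expressing: float = 0.25,
    logfc_cutoff: float = 0.25,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum marker test.

    Only genes expressed in strictly more than ``min_frac_expressing`` of
    the group's cells are tested; BH adjustment runs across the tested
    genes of each group; rows with |logFC| >= ``logfc_cutoff`` are
    reported (logFC = difference of mean log-normalized expression).
    """
    L = _layer_dense(adata, layer)
    groups = np.asarray(adata.obs[groupby])
    frames = []
    for g in pd.unique(groups):
        in_g = groups == g
        if in_g.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        frac = (L[in_g] > 0).mean(axis=0)
        tested = np.flatnonzero(frac > min_frac_expressing)
        if tested.size == 0:
            continue
        a, b = L[in_g][:, tested], L[~in_g][:, tested]
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                 method="asymptotic")
        logfc = a.mean(axis=0) - b.mean(axis=0)
        p_adj = multipletests(res.pvalue, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "group": g,
                "gene": adata.var_names[tested],
                "logFC": logfc,
                "frac_expressing": frac[tested],
                "pvalue": res.pvalue,
                "p_adj": p_adj,
            }
        )
        frames.append(df[np.abs(df["logFC"]) >= logfc_cutoff])
    if not frames:
        return pd.DataFrame(
            columns=["group", "gene", "logFC", "frac_expressing", "pvalue", "p_adj"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "p_adj", "gene"], ignore_index=True)


@dataclass(frozen=True)
class PartitionMetrics:
    ami: float
    ari: float
    silhouette: float
    wss: float


def partition_metrics(
    labels_ref: Sequence, labels_eval: Sequence, embedding: np.ndarray | None = None
) -> PartitionMetrics:
    """Agreement (AMI/ARI between the two labelings) and homogeneity
    (silhouette and within-cluster sum of squares of ``labels_eval`` on
    the embedding).  Silhouette/WSS are NaN when no embedding is given or
    the evaluated partition has a single cluster."""
    labels_ref = np.asarray(labels_ref)
    labels_eval = np.asarray(labels_eval)
    if labels_ref.shape != labels_eval.shape:
        raise ValueError("label vectors must have equal length")
    ami = skm.adjusted_mutual_info_score(labels_ref, labels_eval)
    ari = skm.adjusted_rand_score(labels_ref, labels_eval)
    sil = wss = float("nan")
    if embedding is not None:
        embedding = np.asarray(embedding, dtype=float)
        if embedding.shape[0] != labels_eval.shape[0]:
            raise ValueError("embedding rows must match labels")
        uniq = pd.unique(labels_eval)
        wss = 0.0
        for u in uniq:
            pts = embedding[labels_eval == u]
            wss += float(((pts - pts.mean(axis=0)) ** 2).sum())
        if len(uniq) > 1:
            sil = float(skm.silhouette_score(embedding, labels_eval))
    return PartitionMetrics(ami=float(ami), ari=float(ari), silhouette=sil, wss=wss)


def sweep_partition_metrics(
    labels_ref: Sequence,
    partitions: Mapping[object, Sequence],
    embedding: np.ndarray | None = None,
) -> pd.DataFrame:
    """Evaluate partition_metrics across caller-supplied partitions (e.g.
    clusterings of graphs built at k = 5..50)."""
    rows = []
    for key, labels in partitions.items():
        m = partition_metrics(labels_ref, labels, embedding)
        rows.append(
            {"partition": key, "ami": m.ami, "ari": m.ari,
             "silhouette": m.silhouette, "wss": m.wss}
        )
    return pd.DataFrame(rows)
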