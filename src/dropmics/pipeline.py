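"""End-to-end smoke pipeline: simulate -> qc -> citenorm -> transfer -> da
-> modules, with every stage report serialized as JSON/TSV."""

from __future__ import annotations

import time
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.neighbors import kneighbors_graph

from . import abundance, citeseq, modules, qc, transfer
from .io import truth_to_dict, write_json
from .simulate import (
    FacsGateSpec,
    SimulationConfig,
    generate_multiomic_dataset,
    generate_sorted_timeseries,
)

__all__ = ["run_pipeline", "knn_graph_from_latent"]


def knn_graph_from_latent(latent: np.ndarray, k: int = 30):
    """Symmetric KNN distance graph on a latent embedding."""
    g = kneighbors_graph(latent, n_neighbors=k, mode="distance", include_self=False)
    return g.maximum(g.T)


def _default_configs(seed: int):
    multi = SimulationConfig(
        n_cells=2500,
        n_genes=1200,
        empty_droplet_count=3000,
        n_samples=5,
        seed=seed,
    )
    gates = [
        FacsGateSpec(pi=0.6, s_total=400, s_pos=200) for _ in range(10)
    ]
    series = SimulationConfig(
        n_cells=4000,
        n_genes=300,
        n_samples=10,
        facs_gates=gates,
        seed=seed + 1,
    )
    return multi, series


def run_pipeline(outdir, seed: int = 0, configs=None) -> dict:
    """Run every stage on the default synthetic study and serialize all
    stage reports under ``outdir``.  Returns the collected reports."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    multi_cfg, series_cfg = configs if configs is not None else _default_configs(seed)
    reports: dict = {"seed": seed}

    # --- simulate -----------------------------------------------------
    rna, adt, truth = generate_multiomic_dataset(multi_cfg)
    write_json(truth_to_dict(truth), outdir / "truth.json")

    # --- qc -----------------------------------------------------------
    rna, filt_report = qc.filter_cells_and_genes(rna, min_counts=500, min_genes=100)
    rna, doub_report = qc.remove_doublet_clusters(rna)
    rna = qc.normalize_lognorm(rna)
    hvgs = qc.select_hvgs(rna, n_top=150)
    markers = qc.rank_marker_genes(rna, groupby="cluster_id")
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    reports["qc_filter"] = filt_report.to_dict()
    reports["qc_doublet_clusters"] = doub_report.to_dict()
    reports["n_hvgs"] = len(hvgs)
    write_json(reports["qc_filter"], outdir / "qc_filter.json")
    write_json(reports["qc_doublet_clusters"], outdir / "qc_doublets.json")

    # --- citenorm -----------------------------------------------------
    partition = citeseq.detect_empty_droplets(adt.obs["total_rna_umi"].to_numpy())
    adt = citeseq.dsb_normalize(adt, partition)
    bg_model = citeseq.fit_background_gmm(adt, k_max=8)
    adt = citeseq.compute_bg_scores(adt, bg_model)
    adt = citeseq.regress_background(adt)
    reports["empty_droplets"] = partition.to_dict()
    reports["background_model"] = bg_model.to_dict()
    write_json(reports["empty_droplets"], outdir / "empty_droplets.json")
    write_json(reports["background_model"], outdir / "background_model.json")

    # --- label transfer ----------------------------------------------
    keep = ~np.asarray(rna.obs["cluster_id"] == "doublet")
    clean = rna[keep].copy()
    half = clean.n_obs // 2
    ref, query = clean[:half].copy(), clean[half:].copy()
    ref_markers = qc.rank_marker_genes(ref, groupby="cluster_id")
    features = sorted(set(ref_markers[ref_markers["logFC"] > 0]["gene"]) | set(hvgs[:50]))
    model = transfer.train_transfer_model(
        ref, "cluster_id", features=features,
        l1_grid=(0.0, 0.5, 1.0), alpha_grid=(0.2, 1.0), n_repeats=1,
    )
    preds = transfer.predict_cells(model, query)
    cluster_labels = transfer.assign_cluster_labels(preds, query.obs["cluster_id"])
    impact = transfer.feature_impact(model)
    preds.to_csv(outdir / "predictions.tsv", sep="\t")
    impact.to_csv(outdir / "impact.tsv", sep="\t", index=False)
    reports["transfer"] = {
        "selected_l1_ratio": model.selected_l1_ratio,
        "selected_alpha": model.selected_alpha,
        "assigned_fraction": float((preds["label"] != transfer.UNASSIGNED).mean()),
        "cluster_labels": cluster_labels.to_dict(),
    }
    write_json(reports["transfer"], outdir / "transfer.json")

    # --- differential abundance --------------------------------------
    samples, s_truth = generate_sorted_timeseries(series_cfg)
    ts = ad.concat(samples, label=None)
    graph = knn_graph_from_latent(ts.obsm["X_latent"], k=20)
    nhoods = abundance.build_neighborhoods(
        graph, ts.obs["sample_id"].to_numpy(), prop=0.05, seed=seed
    )
    correction = abundance.facs_correction_factors(s_truth.sample_gates)
    nhood_labels = abundance.label_neighborhoods(nhoods, ts.obs["cell_label"].to_numpy())
    gate_of_label = dict(
        zip(ts.obs["cell_label"].astype(str), ts.obs["facs_gate"].astype(str))
    )
    nhood_gates = nhood_labels.map(lambda l: gate_of_label.get(l, "CD45+"))
    design = (
        ts.obs.groupby("sample_id", observed=True)
        .agg(age_pcw=("age_pcw", "first"), n_cells=("age_pcw", "size"))
    )
    da = abundance.test_differential_abundance(
        nhoods, design, correction=correction, nhood_gates=nhood_gates
    )
    da["label"] = nhood_labels
    da.to_csv(outdir / "neighborhoods.tsv", sep="\t")
    reports["differential_abundance"] = {
        "n_neighborhoods": int(nhoods.n_neighborhoods),
        "n_significant": int((da["spatial_fdr"] < 0.1).sum()),
        "dispersion": float(da["dispersion"].iloc[0]),
    }
    write_json(reports["differential_abundance"], outdir / "da.json")

    # --- module tracking ---------------------------------------------
    ts = qc.normalize_lognorm(ts)
    module_genes = s_truth.marker_genes[sorted(s_truth.marker_genes)[0]]
    score = modules.score_gene_module(ts, module_genes, seed=seed)
    series = modules.enriched_proportion_series(score, ts.obs["age_pcw"].to_numpy())
    series.to_csv(outdir / "module_series.tsv", sep="\t", index=False)
    reports["module_tracking"] = {
        "module_size": len(score.genes),
        "n_controls": len(score.control_genes),
        "series": series.to_dict(orient="records"),
    }
    write_json(reports["module_tracking"], outdir / "modules.json")

    reports["elapsed_seconds"] = time.time() - t0
    write_json(reports, outdir / "pipeline_report.json")
    return reports
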