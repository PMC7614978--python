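"""Parameter-recovery and calibration studies on synthetic data.

Each function runs one self-contained simulation study — the same ones
exercised by the test suite — and returns the measured quantities as a
plain dict.  All randomness is controlled by the ``seed`` argument.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from . import abundance, citeseq, modules, qc, transfer
from .pipeline import knn_graph_from_latent
from .simulate import FacsGateSpec, SimulationConfig, generate_multiomic_dataset, generate_sorted_timeseries

AGE_BINS = (3, 4, 5, 7, 8)


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in ss]


def doublet_rule_study(seed: int = 0, n_runs: int = 100) -> dict:
    """Planted doublet-cluster removal across independent simulations:
    success means exactly the doublet cluster is removed, with no
    collateral cluster loss, in every lane."""
    successes = 0
    for s in _seeds(seed, n_runs):
        cfg = SimulationConfig(n_cells=3000, n_genes=100, n_samples=2,
                               empty_droplet_count=0, seed=s)
        rna, _, _ = generate_multiomic_dataset(cfg)
        _, report = qc.remove_doublet_clusters(rna)
        removed = {
            c for info in report.removed_clusters.values()
            for c in info["removed_clusters"]
        }
        successes += removed == {"doublet"}
    return {"n_runs": n_runs, "successes": successes,
            "success_rate": successes / n_runs}


def doublet_threshold_fixture() -> dict:
    """Hand-computable fixture: cluster score medians {0.05, 0.06, 0.50}."""
    medians = [0.05, 0.06, 0.50]
    scores, clusters = [], []
    for i, m in enumerate(medians):
        scores += [m] * 3
        clusters += [f"cl{i}"] * 3
    adata = ad.AnnData(
        X=np.ones((9, 2)),
        obs=pd.DataFrame(
            {"doublet_score": scores, "cluster_id": clusters, "lane_id": "L0"},
            index=[f"c{i}" for i in range(9)],
        ),
    )
    _, report = qc.remove_doublet_clusters(adata)
    info = report.removed_clusters["L0"]
    return {"threshold": info["threshold"], "removed": info["removed_clusters"]}


def empty_detection_study(seed: int = 0) -> dict:
    """Bimodal droplet mixture: 5000 ambient droplets (log10 UMI ~
    N(2.0, 0.15)) against 3000 cells (N(3.5, 0.2))."""
    cfg = SimulationConfig(n_cells=3000, n_genes=300, empty_droplet_count=5000,
                           seed=seed)
    _, adt, truth = generate_multiomic_dataset(cfg)
    part = citeseq.detect_empty_droplets(adt.obs["total_rna_umi"].to_numpy())
    empties = truth.empty_flags
    return {
        "n_droplets": adt.n_obs,
        "n_bins": part.n_bins,
        "expected_bins": int(round(3.322 * np.log10(adt.n_obs))),
        "sensitivity": float((part.empty_mask & empties).sum() / empties.sum()),
        "cell_misclassification": float(
            (part.empty_mask & ~empties).sum() / (~empties).sum()
        ),
        "fallback": part.fallback,
    }


def dsb_study(seed: int = 0) -> dict:
    """After DSB, ambient droplets are unit z-scores per protein."""
    cfg = SimulationConfig(n_cells=3000, n_genes=300, empty_droplet_count=5000,
                           seed=seed)
    _, adt, _ = generate_multiomic_dataset(cfg)
    part = citeseq.detect_empty_droplets(adt.obs["total_rna_umi"].to_numpy())
    citeseq.dsb_normalize(adt, part)
    D = adt.layers["dsb"][np.asarray(adt.obs["droplet_class"] == "empty")]
    return {
        "n_empty": int(D.shape[0]),
        "mean_abs_max": float(np.abs(D.mean(axis=0)).max()),
        "sd_min": float(D.std(axis=0, ddof=1).min()),
        "sd_max": float(D.std(axis=0, ddof=1).max()),
    }


def gmm_recovery_study(seed: int = 0, n: int = 2000) -> dict:
    """Three well-separated planted clusters in protein space: background
    N(0,1) per protein, two signal populations shifted by +4."""
    rng = np.random.default_rng(seed)
    z = rng.integers(0, 3, n)
    X = rng.normal(0, 1, (n, 3))
    X[z == 1, 0] += 4.0
    X[z == 2, 1] += 4.0
    adata = ad.AnnData(
        X=np.zeros((n, 3)),
        obs=pd.DataFrame({"droplet_class": ["cell"] * n},
                         index=[f"c{i}" for i in range(n)]),
    )
    adata.layers["dsb"] = X
    model = citeseq.fit_background_gmm(adata)
    return {
        "n_cells": n,
        "selected_k": model.selected_k,
        "mu_bg_max_abs_error": float(np.abs(model.mu_bg).max()),
    }


def background_regression_study(seed: int = 0, n: int = 2000, p: int = 4) -> dict:
    """Planted linear background component beta * BG_score on top of the
    true signal; regression must strictly improve signal recovery and
    leave residuals orthogonal to the score."""
    rng = np.random.default_rng(seed)
    truth = rng.normal(0, 1, (n, p))
    score = rng.random(n)
    beta = rng.uniform(0.8, 2.0, p)
    adata = ad.AnnData(
        X=np.zeros((n, p)),
        obs=pd.DataFrame({"droplet_class": ["cell"] * n},
                         index=[f"c{i}" for i in range(n)]),
    )
    adata.layers["dsb"] = truth + np.outer(score, beta)
    adata.obs["bg_score"] = score
    citeseq.regress_background(adata)
    corrected = adata.layers["corrected"]
    gains, covs = [], []
    for j in range(p):
        gains.append(
            np.corrcoef(corrected[:, j], truth[:, j])[0, 1]
            - np.corrcoef(adata.layers["dsb"][:, j], truth[:, j])[0, 1]
        )
        covs.append(abs(np.cov(corrected[:, j], score)[0, 1]))
    return {
        "n_cells": n,
        "min_corr_gain": float(min(gains)),
        "max_abs_residual_cov": float(max(covs)),
    }


def label_transfer_study(seed: int = 0) -> dict:
    """5-class transfer at marker_logfc=1.0 on 3000 cells (1000 reference,
    2000 query): features are reference-DE genes plus HVG nulls; full
    6 x 5 elastic-net grid with 5 splits x 3 repeats."""
    cfg = SimulationConfig(n_cells=3000, n_genes=2000, doublet_rate=0.0,
                           empty_droplet_count=100, seed=seed)
    rna, _, truth = generate_multiomic_dataset(cfg)
    qc.normalize_lognorm(rna)
    rna.obs["state"] = truth.state_labels
    ref, query = rna[:1000].copy(), rna[1000:].copy()
    markers = qc.rank_marker_genes(ref, groupby="state")
    de_genes = set(markers[markers["logFC"] > 0]["gene"])
    hv = set(qc.select_hvgs(ref, n_top=150))
    features = sorted(de_genes | hv)
    model = transfer.train_transfer_model(
        ref, "state", features=features, cv_max_iter=150, cv_tol=2e-3
    )
    preds = transfer.predict_cells(model, query)
    assigned = (preds["label"] != transfer.UNASSIGNED).to_numpy()
    truth_q = np.asarray(query.obs["state"])
    accuracy = float((preds["label"].to_numpy()[assigned] == truth_q[assigned]).mean())

    impact = transfer.feature_impact(model)
    sig = impact[impact["significant"]]
    marker_of = {g: s for s, gs in truth.marker_genes.items() for g in gs}
    planted_pairs = {
        (s, g) for s, gs in truth.marker_genes.items() for g in gs if g in features
    }
    sig_pairs = set(zip(sig["class"], sig["gene"]))
    recall = len(planted_pairs & sig_pairs) / len(planted_pairs)
    precision = (
        sum(1 for c, g in sig_pairs if marker_of.get(g) == c) / len(sig_pairs)
        if sig_pairs
        else 0.0
    )
    return {
        "n_cells": 3000,
        "n_features": len(features),
        "selected_l1_ratio": model.selected_l1_ratio,
        "selected_alpha": model.selected_alpha,
        "accuracy_assigned": accuracy,
        "unassigned_fraction": float(1.0 - assigned.mean()),
        "marker_impact_recall": float(recall),
        "marker_impact_precision": float(precision),
        "n_planted_in_features": len(planted_pairs),
    }


def _sorted_study(seed, frac_pos, pi, props=None, n_samples=15, cells=670,
                  graph_k=30, prop=0.05):
    gates = []
    for j in range(n_samples):
        f = frac_pos[j % len(AGE_BINS)]
        p = pi[j % len(AGE_BINS)] if isinstance(pi, (list, tuple, np.ndarray)) else pi
        gates.append(FacsGateSpec(pi=float(p), s_total=cells,
                                  s_pos=int(round(f * cells))))
    cfg = SimulationConfig(
        n_cells=n_samples * cells, n_genes=50, n_samples=n_samples,
        facs_gates=gates, state_proportions_by_age=props, seed=seed,
    )
    samples, truth = generate_sorted_timeseries(cfg)
    ts = ad.concat(samples)
    graph = knn_graph_from_latent(ts.obsm["X_latent"], k=graph_k)
    nhoods = abundance.build_neighborhoods(
        graph, ts.obs["sample_id"].to_numpy(), prop=prop, seed=seed
    )
    labels = abundance.label_neighborhoods(nhoods, ts.obs["cell_label"].to_numpy())
    gate_of = dict(
        zip(ts.obs["cell_label"].astype(str), ts.obs["facs_gate"].astype(str))
    )
    gates_per_nhood = labels.map(lambda l: gate_of.get(l, "CD45+"))
    design = ts.obs.groupby("sample_id", observed=True).agg(
        age_pcw=("age_pcw", "first"), n_cells=("age_pcw", "size")
    )
    correction = abundance.facs_correction_factors(truth.sample_gates)
    return ts, truth, nhoods, labels, gates_per_nhood, design, correction


def facs_correction_study(seed: int = 0) -> dict:
    """Paired null simulation under age-varying sorting depth: true gate
    proportion pi=0.8 everywhere, sorted CD45+ fraction 0.2..0.6 across
    the five age bins (mean 0.4), no composition change.  The uncorrected
    NB-GLM should show excess false positives; the fs-offset model should
    be calibrated."""
    _, _, nhoods, _, gates_per_nhood, design, correction = _sorted_study(
        seed, frac_pos=[0.2, 0.3, 0.4, 0.5, 0.6], pi=0.8
    )
    plain = abundance.test_differential_abundance(nhoods, design)
    corrected = abundance.test_differential_abundance(
        nhoods, design, correction=correction, nhood_gates=gates_per_nhood
    )
    return {
        "n_neighborhoods": int(nhoods.n_neighborhoods),
        "fpr_uncorrected": float((plain["pvalue"] < 0.05).mean()),
        "fpr_corrected": float((corrected["pvalue"] < 0.05).mean()),
    }


def da_power_study(seed: int = 0) -> dict:
    """A 3-fold increase of one state across gestation (5% -> 15%) with
    unbiased sorting; power is the fraction of that state's neighborhoods
    reaching spatial FDR < 0.1 with a positive age effect."""
    p_last = np.linspace(0.05, 0.15, len(AGE_BINS))
    props = np.zeros((len(AGE_BINS), 5))
    for i, p in enumerate(p_last):
        props[i, :4] = (1 - p) / 4
        props[i, 4] = p
    pis = [float(props[i, :3].sum()) for i in range(len(AGE_BINS))]
    _, _, nhoods, labels, gates_per_nhood, design, correction = _sorted_study(
        seed, frac_pos=pis, pi=pis, props=props, graph_k=100
    )
    res = abundance.test_differential_abundance(
        nhoods, design, correction=correction, nhood_gates=gates_per_nhood
    )
    grown = (labels == "state_4").to_numpy()
    hits = ((res["spatial_fdr"] < 0.1) & (res["logFC"] > 0)).to_numpy()
    return {
        "n_neighborhoods": int(nhoods.n_neighborhoods),
        "n_grown_state_neighborhoods": int(grown.sum()),
        "power": float(hits[grown].mean()),
    }


def module_switch_study(seed: int = 0, n_per_bin: int = 1000) -> dict:
    """Planted temporal enrichment switch (90% -> 10% across five age
    bins) plus the constant-shift invariance of the score itself."""
    rng = np.random.default_rng(seed)
    enriched_frac = [0.9, 0.7, 0.5, 0.3, 0.1]
    n, g = n_per_bin * len(AGE_BINS), 2000
    layer = rng.normal(1.0, 0.3, (n, g))
    ages = np.repeat(AGE_BINS, n_per_bin).astype(float)
    flags = np.zeros(n, bool)
    for a, f in zip(AGE_BINS, enriched_frac):
        members = np.flatnonzero(ages == a)
        flags[rng.choice(members, int(f * n_per_bin), replace=False)] = True
    layer[np.ix_(flags, np.arange(10))] += 0.8
    layer[np.ix_(~flags, np.arange(10))] -= 0.8
    adata = ad.AnnData(
        X=np.ones((n, g)),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
    )
    adata.layers["lognorm"] = layer
    genes = [f"g{j}" for j in range(10)]
    score = modules.score_gene_module(adata, genes, seed=seed)
    series = modules.enriched_proportion_series(score, ages)
    max_err = float(np.abs(series["proportion"].to_numpy() - enriched_frac).max())

    shifted = adata.copy()
    shifted.layers["lognorm"] = layer + 3.1
    score2 = modules.score_gene_module(shifted, genes, seed=seed)
    shift_err = float(np.abs(score.scores - score2.scores).max())
    return {
        "n_cells": n,
        "proportions": series["proportion"].tolist(),
        "planted": enriched_frac,
        "max_abs_error": max_err,
        "shift_invariance_error": shift_err,
    }
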