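"""CITE-seq antibody background normalization.

The chain has a fixed order, each stage reading only layers written by
earlier ones:

1. :func:`detect_empty_droplets` — find the ambient (empty-droplet) peak
   of the log10 total-RNA-UMI histogram and class droplets under it as
   empty.
2. :func:`dsb_normalize` — z-score log1p protein counts against the
   empty-droplet (ambient) distribution per protein ("dsb" layer).
3. :func:`fit_background_gmm` — Gaussian mixtures over cells in protein
   space for k = 2..21, selected by BIC (AIC recorded); the smallest
   component mean per protein is the background mean mu_bg.
4. :func:`compute_bg_scores` — per-cell background score
   mean_p exp(mu_bg_p - x_cp), min-max scaled to [0, 1].
5. :func:`regress_background` — per-protein Gaussian linear regression of
   the dsb value on the background score; the "corrected" layer keeps
   residuals plus the fitted intercept, removing the background-associated
   component while preserving location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
from scipy import sparse, signal
from sklearn.mixture import GaussianMixture

__all__ = [
    "DropletPartition",
    "BackgroundModel",
    "detect_empty_droplets",
    "dsb_normalize",
    "fit_background_gmm",
    "compute_bg_scores",
    "regress_background",
]


@dataclass
class DropletPartition:
    """Outcome of empty-droplet peak detection on log10 total UMI."""

    n_bins: int
    peak_positions: np.ndarray
    peak_heights: np.ndarray
    empty_threshold: float  # mu_UMI - 1.96 * std on the log10 axis
    empty_peak_position: float | None
    boundary: float | None  # log10-UMI right boundary of the empty peak
    empty_mask: np.ndarray
    fallback: bool

    @property
    def empty_indices(self) -> np.ndarray:
        return np.flatnonzero(self.empty_mask)

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "n_empty": int(self.empty_mask.sum()),
            "empty_threshold": self.empty_threshold,
            "empty_peak_position": self.empty_peak_position,
            "boundary": self.boundary,
            "fallback": self.fallback,
        }


@dataclass
class BackgroundModel:
    """BIC/AIC-selected Gaussian mixture background model."""

    k_range: tuple[int, ...]
    bic: dict[int, float]
    aic: dict[int, float]
    selected_k: int
    component_means: np.ndarray  # (k, n_proteins)
    component_weights: np.ndarray
    mu_bg: np.ndarray  # per-protein minimum component mean
    log_likelihood: float
    n_cells: int
    per_protein: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "bic": {str(k): v for k, v in self.bic.items()},
            "aic": {str(k): v for k, v in self.aic.items()},
            "selected_k": self.selected_k,
            "mu_bg": self.mu_bg.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_cells": self.n_cells,
            "notes": self.notes,
        }


def n_histogram_bins(n_droplets: int) -> int:
    """Sturges-like bin count round(3.322 * log10(X)); 3.322 ~ 1/log10(2)."""
    return int(round(3.322 * np.log10(n_droplets)))


def detect_empty_droplets(
    total_umi: np.ndarray,
    prominences: range = range(0, 21),
    widths: range = range(0, 11),
) -> DropletPartition:
    """Partition droplets into ambient (empty) and cell-containing.

    A histogram of log10(1 + UMI) is built at round(3.322*log10(X)) bins
    and peaks are collected over a sweep of integer prominence (0..20)
    crossed with width (0..10) settings.  The empty peak is the tallest
    peak positioned below mu_UMI - 1.96*std (mean/sd on the log10 axis);
    when no peak satisfies that and at least two peaks exist, the tallest
    peak strictly below mu_UMI is taken instead (the mixture's own spread
    makes the 1.96-sigma cut unreachable whenever ambient droplets hold a
    substantial share of the lane).  Droplets at or below the histogram
    valley separating the empty peak from the next peak to its right are
    classed empty.  With no usable peak the fallback applies: droplets
    below mu_UMI - 1.96*std are empty, and the fallback flag is set.
    """
    total_umi = np.asarray(total_umi, dtype=float).ravel()
    X = total_umi.size
    if X < 100:
        raise ValueError(f"need at least 100 droplets, got {X}")
    log_umi = np.log10(1.0 + total_umi)
    n_bins = n_histogram_bins(X)
    if n_bins < 2 or np.ptp(log_umi) == 0:
        mu, sd = log_umi.mean(), log_umi.std(ddof=1) if X > 1 else 0.0
        thr = mu - 1.96 * sd
        return DropletPartition(
            n_bins=n_bins,
            peak_positions=np.empty(0),
            peak_heights=np.empty(0),
            empty_threshold=thr,
            empty_peak_position=None,
            boundary=None,
            empty_mask=log_umi < thr,
            fallback=True,
        )
    hist, edges = np.histogram(log_umi, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = float(log_umi.mean())
    sd = float(log_umi.std(ddof=1))
    threshold = mu - 1.96 * sd

    peak_idx: set[int] = set()
    for prom in prominences:
        for wid in widths:
            found, _ = signal.find_peaks(hist, prominence=prom, width=wid)
            peak_idx.update(int(i) for i in found)
    peaks = np.asarray(sorted(peak_idx), dtype=int)
    positions = centers[peaks] if peaks.size else np.empty(0)
    heights = hist[peaks].astype(float) if peaks.size else np.empty(0)

    empty_peak = None
    qualifying = peaks[positions < threshold] if peaks.size else np.empty(0, int)
    if qualifying.size:
        empty_peak = int(qualifying[np.argmax(hist[qualifying])])
    elif peaks.size >= 2:
        below_mean = peaks[positions < mu]
        if below_mean.size:
            empty_peak = int(below_mean[np.argmax(hist[below_mean])])

    if empty_peak is None:
        return DropletPartition(
            n_bins=n_bins,
            peak_positions=positions,
            peak_heights=heights,
            empty_threshold=threshold,
            empty_peak_position=None,
            boundary=None,
            empty_mask=log_umi < threshold,
            fallback=True,
        )

    right_peaks = peaks[peaks > empty_peak]
    if right_peaks.size:
        nxt = int(right_peaks.min())
        valley = empty_peak + int(np.argmin(hist[empty_peak : nxt + 1]))
        boundary = float(centers[valley])
    else:
        # no peak to the right: extend by the half-prominence half-width
        w, _, _, right_ips = signal.peak_widths(hist, [empty_peak], rel_height=0.5)
        bin_width = edges[1] - edges[0]
        boundary = float(edges[0] + right_ips[0] * bin_width)
    return DropletPartition(
        n_bins=n_bins,
        peak_positions=positions,
        peak_heights=heights,
        empty_threshold=threshold,
        empty_peak_position=float(centers[empty_peak]),
        boundary=boundary,
        empty_mask=log_umi <= boundary,
        fallback=False,
    )


def _counts_dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def dsb_normalize(
    adata: ad.AnnData,
    partition: DropletPartition,
    min_empty: int = 50,
    layer: str = "dsb",
) -> ad.AnnData:
    """Denoise-and-scale-by-background: per protein, z-score log1p counts
    against the empty-droplet ambient distribution.  The layer is written
    for every droplet; the droplet class is recorded in
    ``obs['droplet_class']``."""
    empty = np.asarray(partition.empty_mask, dtype=bool)
    if empty.size != adata.n_obs:
        raise ValueError("partition does not match the assay")
    n_empty = int(empty.sum())
    if n_empty < min_empty:
        raise ValueError(
            f"need at least {min_empty} empty droplets for DSB, found {n_empty}"
        )
    L = np.log1p(_counts_dense(adata))
    mu = L[empty].mean(axis=0)
    sd = L[empty].std(axis=0, ddof=1)
    degenerate = sd < 1e-8
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} protein(s) have zero ambient variance; "
            "sd floored at 1e-8"
        )
        sd = np.where(degenerate, 1e-8, sd)
    adata.layers[layer] = (L - mu) / sd
    adata.obs["droplet_class"] = np.where(empty, "empty", "cell")
    adata.uns["dsb_ambient_mean"] = mu
    adata.uns["dsb_ambient_sd"] = sd
    return adata


def _cell_matrix(adata: ad.AnnData, layer: str) -> tuple[np.ndarray, np.ndarray]:
    if layer not in adata.layers:
        raise KeyError(f"layer {layer!r} missing; run dsb_normalize first")
    cells = np.asarray(adata.obs["droplet_class"] == "cell")
    M = adata.layers[layer]
    M = M.toarray() if sparse.issparse(M) else np.asarray(M, dtype=float)
    return M, cells


def fit_background_gmm(
    adata: ad.AnnData,
    k_min: int = 2,
    k_max: int = 21,
    seed: int = 0,
    n_init: int = 5,
    per_protein: bool = False,
    layer: str = "dsb",
) -> BackgroundModel:
    """Fit diagonal-covariance Gaussian mixtures over cells in protein
    space for k = k_min..k_max and select k by BIC (AIC recorded; a
    disagreement is noted).  ``mu_bg`` is, per protein, the smallest
    component mean of the selected model.

    With ``per_protein=True`` an independent univariate mixture is fitted
    to each protein instead, and mu_bg collects each protein's smallest
    selected component mean (BIC summed across proteins per k).
    """
    M, cells = _cell_matrix(adata, layer)
    Xc = M[cells]
    notes: list[str] = []
    ks = tuple(range(k_min, k_max + 1))

    def _fit(data: np.ndarray):
        bic, aic, models = {}, {}, {}
        for k in ks:
            try:
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="diag",
                    n_init=n_init,
                    random_state=seed,
                )
                gm.fit(data)
            except Exception as err:  # non-convergence at this k
                notes.append(f"k={k} skipped: {err}")
                continue
            bic[k], aic[k], models[k] = gm.bic(data), gm.aic(data), gm
        if not models:
            raise RuntimeError("no mixture converged at any k")
        return bic, aic, models

    if not per_protein:
        bic, aic, models = _fit(Xc)
        best_k = min(bic, key=bic.get)
        if min(aic, key=aic.get) != best_k:
            notes.append(
                f"AIC prefers k={min(aic, key=aic.get)} but BIC k={best_k}; BIC used"
            )
        gm = models[best_k]
        mu_bg = gm.means_.min(axis=0)
        model = BackgroundModel(
            k_range=ks,
            bic=bic,
            aic=aic,
            selected_k=best_k,
            component_means=gm.means_,
            component_weights=gm.weights_,
            mu_bg=mu_bg,
            log_likelihood=float(gm.score(Xc) * Xc.shape[0]),
            n_cells=int(Xc.shape[0]),
            per_protein=False,
            notes=notes,
        )
    else:
        mu_bg = np.empty(Xc.shape[1])
        bic_sum: dict[int, float] = {k: 0.0 for k in ks}
        aic_sum: dict[int, float] = {k: 0.0 for k in ks}
        sel = []
        ll = 0.0
        for p in range(Xc.shape[1]):
            bic, aic, models = _fit(Xc[:, [p]])
            for k in bic:
                bic_sum[k] += bic[k]
                aic_sum[k] += aic[k]
            best_k = min(bic, key=bic.get)
            sel.append(best_k)
            gm = models[best_k]
            mu_bg[p] = gm.means_.min()
            ll += float(gm.score(Xc[:, [p]]) * Xc.shape[0])
        best_k = int(np.median(sel))
        model = BackgroundModel(
            k_range=ks,
            bic=bic_sum,
            aic=aic_sum,
            selected_k=best_k,
            component_means=np.empty((0, Xc.shape[1])),
            component_weights=np.empty(0),
            mu_bg=mu_bg,
            log_likelihood=ll,
            n_cells=int(Xc.shape[0]),
            per_protein=True,
            notes=notes,
        )
    adata.uns["background_model"] = model.to_dict()
    return model


def compute_bg_scores(
    adata: ad.AnnData,
    model: BackgroundModel,
    agg: str = "mean",
    layer: str = "dsb",
    key: str = "bg_score",
) -> ad.AnnData:
    """Per-cell background score: exp(mu_bg_p - x_cp) aggregated across
    proteins (mean by default, median optional), then min-max scaled to
    [0, 1] over cells.  Scores inversely order with expression: the more
    a cell expresses above background, the lower its score."""
    M, cells = _cell_matrix(adata, layer)
    ratios = np.exp(model.mu_bg[None, :] - M)
    if agg == "mean":
        raw = ratios.mean(axis=1)
    elif agg == "median":
        raw = np.median(ratios, axis=1)
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    cell_raw = raw[cells]
    lo, hi = cell_raw.min(), cell_raw.max()
    scores = np.full(adata.n_obs, np.nan)
    if hi == lo:
        warnings.warn("all background scores identical; set to 0")
        scores[cells] = 0.0
    else:
        scores[cells] = (raw[cells] - lo) / (hi - lo)
    adata.obs[key] = scores
    return adata


def regress_background(
    adata: ad.AnnData,
    layer: str = "dsb",
    out_layer: str = "corrected",
    score_key: str = "bg_score",
) -> ad.AnnData:
    """Per protein, ordinary Gaussian linear regression of the dsb value
    on the background score across cells; the corrected layer keeps
    residuals + fitted intercept.  By least squares, the corrected values
    have zero sample covariance with the score."""
    M, cells = _cell_matrix(adata, layer)
    if score_key not in adata.obs:
        raise KeyError(f"obs[{score_key!r}] missing; run compute_bg_scores first")
    s = adata.obs[score_key].to_numpy(dtype=float)[cells]
    Y = M[cells]
    corrected = np.array(M)
    sc = s - s.mean()
    denom = float(sc @ sc)
    if denom < 1e-12:
        warnings.warn("background score is constant; regression skipped")
        adata.layers[out_layer] = corrected
        return adata
    slope = (sc @ (Y - Y.mean(axis=0))) / denom
    intercept = Y.mean(axis=0) - slope * s.mean()
    corrected[cells] = Y - np.outer(s, slope)  # residuals + intercept
    adata.layers[out_layer] = corrected
    adata.uns["background_regression"] = {
        "slope": slope.tolist(),
        "intercept": intercept.tolist(),
    }
    return adata
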