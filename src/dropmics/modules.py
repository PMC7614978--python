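"""Gene-module enrichment scoring and temporal tracking.

A module score is the per-cell mean log-normalized expression of a gene
set minus the mean of expression-matched control genes: genes are cut
into equal-frequency bins by mean expression and, for each module gene,
``ctrl_size`` controls are sampled from its bin (module genes themselves
are excluded from the control pool by default).  A cell is "enriched"
when its score is strictly positive.  Enriched proportions are tracked
across gestational age bins, restricted to eligible cells (for
single-gene tracking, cells with > 0 log-normalized counts of the gene),
and enrichment scores can be standardized robustly by (x - median)/MAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ModuleScore",
    "score_gene_module",
    "enriched_proportion_series",
    "single_gene_series",
    "robust_standardize",
]


@dataclass
class ModuleScore:
    genes: list[str]
    control_genes: list[str]
    ctrl_size: int
    n_bins: int
    seed: int
    scores: np.ndarray  # per-cell raw score

    @property
    def enriched(self) -> np.ndarray:
        return self.scores > 0


def _layer(adata: ad.AnnData, layer: str) -> np.ndarray:
    if layer not in adata.layers:
        raise KeyError(f"layer {layer!r} missing; run normalize_lognorm first")
    M = adata.layers[layer]
    return M.toarray() if sparse.issparse(M) else np.asarray(M, dtype=float)


def score_gene_module(
    adata: ad.AnnData,
    genes,
    ctrl_size: int = 200,
    n_bins: int = 50,
    seed: int = 0,
    layer: str = "lognorm",
    exclude_module_genes: bool = True,
) -> ModuleScore:
    """Score = mean(module expression) - mean(binned-control expression)
    per cell.  Deterministic under a fixed seed and invariant to gene
    column order (genes are handled by name, bins tie-broken by stable
    name order)."""
    genes = [str(g) for g in genes]
    present = [g for g in genes if g in adata.var_names]
    dropped = set(genes) - set(present)
    if dropped:
        warnings.warn(f"{len(dropped)} module gene(s) absent and dropped")
    if not present:
        raise ValueError("no module genes present in the data")

    L = _layer(adata, layer)
    var_order = np.argsort(adata.var_names)  # name order, not column order
    names = np.asarray(adata.var_names)[var_order]
    means = L.mean(axis=0)[var_order]
    ranks = pd.Series(means).rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(means)), labels=False, duplicates="drop")

    bin_of = dict(zip(names, bins))
    module_set = set(present)
    rng = np.random.default_rng(seed)
    controls: set[str] = set()
    for g in sorted(present):
        b = bin_of[g]
        pool = names[bins == b]
        if exclude_module_genes:
            pool = np.array([x for x in pool if x not in module_set])
        if pool.size == 0:
            continue
        take = min(ctrl_size, pool.size)
        controls.update(rng.choice(pool, size=take, replace=False).tolist())
    control_genes = sorted(controls)
    col = {g: i for i, g in enumerate(adata.var_names)}
    mod_idx = [col[g] for g in present]
    if control_genes:
        ctrl_idx = [col[g] for g in control_genes]
        scores = L[:, mod_idx].mean(axis=1) - L[:, ctrl_idx].mean(axis=1)
    else:
        warnings.warn("empty control pool; score is the raw module mean")
        scores = L[:, mod_idx].mean(axis=1)
    return ModuleScore(
        genes=present,
        control_genes=control_genes,
        ctrl_size=ctrl_size,
        n_bins=n_bins,
        seed=seed,
        scores=scores,
    )


def enriched_proportion_series(
    score: ModuleScore,
    ages,
    population_mask=None,
    eligibility=None,
) -> pd.DataFrame:
    """Per age bin: the proportion of eligible cells of the population
    with a strictly positive module score.

    ``population_mask`` restricts to the population of interest and
    ``eligibility`` (e.g. detectable expression of a tracked gene)
    gates which cells enter the denominator.  Bins are ordered by age;
    an empty bin yields NaN.  Enriched counts are carried so that plots
    can size or hide symbols below a display threshold without touching
    the data.
    """
    ages = np.asarray(ages, dtype=float)
    n = score.scores.size
    if ages.size != n:
        raise ValueError("ages must give one value per cell")
    mask = np.ones(n, dtype=bool) if population_mask is None else np.asarray(population_mask, bool)
    elig = np.ones(n, dtype=bool) if eligibility is None else np.asarray(eligibility, bool)
    keep = mask & elig
    enriched = score.enriched
    rows = []
    for a in np.unique(ages):
        members = keep & (ages == a)
        n_elig = int(members.sum())
        n_enr = int((enriched & members).sum())
        rows.append(
            {
                "age_pcw": a,
                "n_eligible": n_elig,
                "n_enriched": n_enr,
                "proportion": n_enr / n_elig if n_elig else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("age_pcw", ignore_index=True)


def single_gene_series(
    adata: ad.AnnData,
    gene: str,
    ages_key: str = "age_pcw",
    population_mask=None,
    ctrl_size: int = 200,
    n_bins: int = 50,
    seed: int = 0,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Track one gene (e.g. a globin) across age: a singleton module score
    with eligibility restricted to cells with > 0 log-normalized counts
    of that gene."""
    score = score_gene_module(
        adata, [gene], ctrl_size=ctrl_size, n_bins=n_bins, seed=seed, layer=layer
    )
    L = _layer(adata, layer)
    gi = list(adata.var_names).index(gene)
    eligibility = L[:, gi] > 0
    return enriched_proportion_series(
        score,
        adata.obs[ages_key].to_numpy(),
        population_mask=population_mask,
        eligibility=eligibility,
    )


def robust_standardize(values) -> np.ndarray:
    """(x - median) / MAD with unscaled MAD (no 1.4826 factor)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("robust_standardize needs at least 2 distinct values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError(
            "MAD is zero (more than half the values equal the median); "
            "robust standardization is undefined for this input"
        )
    return (x - med) / mad
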