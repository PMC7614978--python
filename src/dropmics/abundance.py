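"""KNN-neighborhood differential abundance across gestation.

Neighborhoods are index cells plus their graph neighbors, sampled at a
proportion of all cells.  Per-neighborhood cell counts per sample are
modeled with a negative-binomial GLM on gestational age (continuous, in
post-conception weeks) with a log total-cell offset; a per-(sample, gate)
FACS isolation factor fs = log(pi * S / Si) enters the offset to absorb
sorting bias, and p-values receive a spatial FDR correction — a weighted
Benjamini-Hochberg with weights reciprocal to each neighborhood's index
cell k-distance.

On the offset sign: a gate sorted at observed fraction Si/S when its true
proportion is pi multiplies that gate's expected neighborhood counts by
Si / (pi * S) = exp(-fs), so the absorbing offset is log(N_s) - fs.
Adding fs instead would double the distortion; with unbiased sorting
(fs = 0) either form reduces exactly to the uncorrected model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse

__all__ = [
    "NeighborhoodSet",
    "FacsCorrection",
    "build_neighborhoods",
    "facs_correction_factors",
    "test_differential_abundance",
    "label_neighborhoods",
    "weighted_bh",
]

MIXED = "Mixed"


@dataclass
class NeighborhoodSet:
    index_cells: np.ndarray  # positions of the sampled index cells
    membership: sparse.csr_matrix  # neighborhood x cell incidence
    counts: pd.DataFrame  # neighborhood x sample cell counts
    k_distances: np.ndarray  # index cell's distance to its farthest neighbor

    @property
    def n_neighborhoods(self) -> int:
        return self.membership.shape[0]

    def sizes(self) -> np.ndarray:
        return np.asarray(self.membership.sum(axis=1)).ravel()


@dataclass
class FacsCorrection:
    """Per-(sample, gate) isolation factors fs = log(pi * S / Si)."""

    table: pd.DataFrame  # sample_id, gate, pi, S, Si, fs

    def fs_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (r.sample_id, r.gate): r.fs for r in self.table.itertuples(index=False)
        }


def build_neighborhoods(
    graph: sparse.spmatrix,
    samples,
    prop: float = 0.05,
    seed: int = 0,
) -> NeighborhoodSet:
    """Sample round(prop * n_cells) index cells without replacement and
    take each index cell plus its graph neighbors as a neighborhood.

    ``graph`` is a (cells x cells) sparse KNN adjacency whose stored
    values, when not all 1, are interpreted as distances (the k-distance
    of an index cell is its largest stored neighbor distance; for a
    binary graph all k-distances are 1, i.e. equal spatial-FDR weights).
    """
    if not 0.0 < prop <= 1.0:
        raise ValueError(f"prop must lie in (0, 1], got {prop}")
    graph = sparse.csr_matrix(graph)
    n = graph.shape[0]
    samples = np.asarray(samples)
    if samples.size != n:
        raise ValueError("samples must give one sample id per cell")
    n_index = int(round(prop * n))
    rng = np.random.default_rng(seed)
    index_cells = np.sort(rng.choice(n, size=n_index, replace=False))

    rows, cols = [], []
    k_dist = np.ones(n_index)
    for i, c in enumerate(index_cells):
        nbrs = graph.indices[graph.indptr[c] : graph.indptr[c + 1]]
        vals = graph.data[graph.indptr[c] : graph.indptr[c + 1]]
        members = np.union1d(nbrs, [c])
        rows.extend([i] * members.size)
        cols.extend(members.tolist())
        if vals.size:
            k_dist[i] = float(vals.max())
    membership = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_index, n)
    )
    sample_levels = pd.unique(samples)
    onehot = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), pd.Categorical(samples, categories=sample_levels).codes)),
        shape=(n, len(sample_levels)),
    )
    counts = pd.DataFrame(
        (membership @ onehot).toarray(),
        columns=sample_levels,
        index=[f"nhood{i}" for i in range(n_index)],
    )
    return NeighborhoodSet(
        index_cells=index_cells,
        membership=membership,
        counts=counts,
        k_distances=k_dist,
    )


def facs_correction_factors(sample_table: pd.DataFrame) -> FacsCorrection:
    """fs = log(pi * S / Si), natural log, per (sample, gate).

    ``sample_table`` needs columns sample_id, gate, pi, S, Si.  fs is 0
    exactly when the sorted fraction Si/S equals the true proportion pi.
    """
    required = {"sample_id", "gate", "pi", "S", "Si"}
    missing = required - set(sample_table.columns)
    if missing:
        raise KeyError(f"sample_table missing columns {sorted(missing)}")
    t = sample_table.copy()
    pi = t["pi"].to_numpy(dtype=float)
    S = t["S"].to_numpy(dtype=float)
    Si = t["Si"].to_numpy(dtype=float)
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("pi must lie strictly in (0, 1)")
    if np.any(Si <= 0):
        raise ValueError("Si must be positive")
    t["fs"] = np.log(pi * S / Si)
    return FacsCorrection(table=t)


def _common_dispersion(Y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB2 dispersion pooled across neighborhoods:
    solve Var = mu + alpha * mu^2 from Poisson-fitted means."""
    resid2 = (Y - mu) ** 2 - mu
    denom = float((mu**2).sum())
    if denom <= 0:
        return 1e-8
    return float(max(resid2.sum() / denom, 1e-8))


def test_differential_abundance(
    nhoods: NeighborhoodSet,
    design: pd.DataFrame,
    correction: FacsCorrection | None = None,
    nhood_gates: pd.Series | np.ndarray | None = None,
    fdr_weights: str = "k_distance",
    test: str = "wald",
) -> pd.DataFrame:
    """Per-neighborhood NB-GLM of counts on age with offsets.

    ``design`` is indexed by sample id with columns ``age_pcw`` and
    optionally ``n_cells`` (total cells per sample; defaults to the
    neighborhood-count column sums).  When a FACS correction and the
    per-neighborhood gate assignment are supplied, each neighborhood's
    per-sample offset becomes log(n_cells) - fs(sample, gate).

    Returns a DataFrame with logFC (the age slope, natural log per week),
    p-value, and the spatial FDR (weighted BH, weights 1/k-distance).
    """
    if "age_pcw" not in design.columns:
        raise ValueError("design must contain an 'age_pcw' column")
    samples = list(nhoods.counts.columns)
    design = design.loc[samples]
    age = design["age_pcw"].to_numpy(dtype=float)
    if np.allclose(age, age[0]):
        raise ValueError("age covariate does not vary across samples")
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    n_cells = (
        design["n_cells"].to_numpy(dtype=float)
        if "n_cells" in design.columns
        else nhoods.counts.to_numpy().sum(axis=0)
    )
    base_offset = np.log(n_cells)

    fs_matrix = np.zeros((nhoods.n_neighborhoods, len(samples)))
    if correction is not None:
        if nhood_gates is None:
            raise ValueError(
                "FACS correction requires the per-neighborhood gate assignment"
            )
        lookup = correction.fs_lookup()
        gates = np.asarray(nhood_gates)
        for i, g in enumerate(gates):
            fs_matrix[i] = [lookup.get((s, g), 0.0) for s in samples]

    X = sm.add_constant(age)
    Y = nhoods.counts.to_numpy(dtype=float)

    # stage 1: Poisson fits for the pooled method-of-moments dispersion
    mu = np.empty_like(Y)
    ok = np.ones(Y.shape[0], dtype=bool)
    fits_offset = base_offset[None, :] - fs_matrix
    for i in range(Y.shape[0]):
        try:
            res = sm.GLM(
                Y[i], X, family=sm.families.Poisson(), offset=fits_offset[i]
            ).fit()
            mu[i] = res.fittedvalues
        except Exception:
            ok[i] = False
            mu[i] = np.nan
    alpha = _common_dispersion(Y[ok], mu[ok]) if ok.any() else 1e-8

    logfc = np.full(Y.shape[0], np.nan)
    pval = np.full(Y.shape[0], np.nan)
    fam = sm.families.NegativeBinomial(alpha=alpha)
    for i in range(Y.shape[0]):
        if not ok[i]:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(Y[i], X, family=fam, offset=fits_offset[i]).fit()
            logfc[i] = res.params[1]
            if test == "wald":
                pval[i] = res.pvalues[1]
            elif test == "lrt":
                null = sm.GLM(
                    Y[i], X[:, :1], family=fam, offset=fits_offset[i]
                ).fit()
                lr = 2.0 * (res.llf - null.llf)
                from scipy.stats import chi2

                pval[i] = float(chi2.sf(max(lr, 0.0), df=1))
            else:
                raise ValueError(f"unknown test {test!r}")
        except ValueError:
            raise
        except Exception:
            ok[i] = False

    weights = (
        1.0 / nhoods.k_distances
        if fdr_weights == "k_distance"
        else np.ones(Y.shape[0])
    )
    spatial_fdr = weighted_bh(pval, weights)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "pvalue": pval,
            "spatial_fdr": spatial_fdr,
            "converged": ok,
            "dispersion": alpha,
        },
        index=nhoods.counts.index,
    )


def weighted_bh(pvalues: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Benjamini-Hochberg step-up adjustment.

    Sorting p ascending with cumulative weights w_(1..i), the adjusted
    value is min over j >= i of (sum(w) * p_(j) / cumw_(j)), clipped at 1.
    With equal weights this is exactly classical BH.  NaNs pass through.
    """
    p = np.asarray(pvalues, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("weights must match p-values")
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    ps, ws = p[mask], w[mask]
    order = np.argsort(ps, kind="stable")
    cumw = np.cumsum(ws[order])
    raw = ws.sum() * ps[order] / cumw
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    res = np.empty_like(ps)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def label_neighborhoods(nhoods: NeighborhoodSet, cell_labels) -> pd.Series:
    """Majority vote: a neighborhood takes the modal member label when its
    frequency strictly exceeds 50%, else "Mixed"."""
    labels = np.asarray(cell_labels)
    if labels.size != nhoods.membership.shape[1]:
        raise ValueError("cell_labels must give one label per cell")
    out = []
    M = nhoods.membership
    for i in range(M.shape[0]):
        members = M.indices[M.indptr[i] : M.indptr[i + 1]]
        if members.size == 0:
            raise ValueError(f"neighborhood {i} is empty")
        counts = pd.Series(labels[members]).value_counts()
        out.append(
            counts.index[0] if counts.iloc[0] / members.size > 0.5 else MIXED
        )
    return pd.Series(out, index=nhoods.counts.index, name="nhood_label")
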