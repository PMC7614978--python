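"""Probabilistic elastic-net label transfer.

A multinomial logistic regression with elastic-net penalty is tuned over
a fixed grid of l1_ratio values (0, 0.2, 0.4, 0.6, 0.8, 1) crossed with
alpha values (0.2, 0.4, 0.6, 0.8, 1), alpha acting as the inverse of the
regularization strength.  Model selection uses 5 stratified train/test
splits repeated 3 times; the fold score is the class-frequency-weighted
mean squared error between one-hot labels and predicted probabilities,
and the grid point minimizing the unweighted mean over the 15 fold
scores is refitted on all data.

Query cells inherit the argmax class only when its probability reaches
the decision threshold (0.9); clusters inherit the modal projected label
only when its count strictly exceeds mean + 1*std of the cluster's label
counts.  Per-class feature impact scores are e^coefficient, with
significance from the survival function of a normal fitted to the
class's coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "TransferModel",
    "train_transfer_model",
    "predict_cells",
    "assign_cluster_labels",
    "feature_impact",
    "UNASSIGNED",
    "UNRESOLVED",
]

UNASSIGNED = "unassigned"
UNRESOLVED = "unresolved"

L1_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
ALPHA_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class TransferModel:
    classes: np.ndarray
    features: list[str]
    coef: np.ndarray  # (n_classes, n_features) in multinomial form
    intercept: np.ndarray
    cv_results: pd.DataFrame  # l1_ratio, alpha, repeat, fold, mse
    selected_l1_ratio: float
    selected_alpha: float
    decision_threshold: float = 0.9
    binary: bool = False
    notes: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = X @ self.coef.T + self.intercept
        if self.binary:
            p1 = 1.0 / (1.0 + np.exp(-Z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return E / E.sum(axis=1, keepdims=True)

    def summary(self) -> pd.DataFrame:
        """Mean cross-validated MSE per grid point."""
        return (
            self.cv_results.groupby(["l1_ratio", "alpha"])["mse"]
            .mean()
            .reset_index()
            .sort_values("mse", ignore_index=True)
        )


def _matrix(adata: ad.AnnData, features: list[str], layer: str) -> np.ndarray:
    missing = [f for f in features if f not in adata.var_names]
    if len(missing) == len(features):
        raise ValueError("no model features found in the data")
    if missing:
        warnings.warn(f"{len(missing)} model features absent; zero-filled")
    L = adata.layers[layer]
    L = L.toarray() if sparse.issparse(L) else np.asarray(L, dtype=float)
    col = {g: i for i, g in enumerate(adata.var_names)}
    X = np.zeros((adata.n_obs, len(features)))
    for j, f in enumerate(features):
        if f in col:
            X[:, j] = L[:, col[f]]
    return X


def _new_estimator(l1_ratio: float, alpha: float, max_iter: int, tol: float):
    # alpha is the inverse of the regularization strength, i.e. C;
    # a float l1_ratio implies the elastic-net penalty
    return LogisticRegression(
        solver="saga",
        C=alpha,
        l1_ratio=l1_ratio,
        max_iter=max_iter,
        tol=tol,
        random_state=0,
    )


def weighted_mse(y_onehot: np.ndarray, proba: np.ndarray) -> float:
    """Class-frequency-weighted MSE between one-hot labels and predicted
    probabilities: per-class mean squared error, averaged with weights
    equal to the class frequencies in the fold."""
    n = y_onehot.shape[0]
    total = 0.0
    for c in range(y_onehot.shape[1]):
        members = y_onehot[:, c] == 1
        if not members.any():
            continue
        mse_c = float(((proba[members] - y_onehot[members]) ** 2).mean())
        total += (members.sum() / n) * mse_c
    return total


def cv_fold_indices(y: np.ndarray, n_splits: int = 5, n_repeats: int = 3):
    """Deterministic stratified folds; repeat r uses seed r (0, 1, 2)."""
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=r)
        for f, (tr, te) in enumerate(skf.split(np.zeros_like(y), y)):
            yield r, f, tr, te


def train_transfer_model(
    ref: ad.AnnData,
    label_key: str,
    features: list[str],
    layer: str = "lognorm",
    l1_grid: tuple[float, ...] = L1_GRID,
    alpha_grid: tuple[float, ...] = ALPHA_GRID,
    n_splits: int = 5,
    n_repeats: int = 3,
    decision_threshold: float = 0.9,
    cv_max_iter: int = 300,
    cv_tol: float = 1e-3,
    final_max_iter: int = 2000,
    final_tol: float = 1e-4,
) -> TransferModel:
    """Tune and fit the elastic-net classifier on a labeled reference."""
    y = np.asarray(ref.obs[label_key]).astype(str)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < n_splits:
        bad = classes[counts < n_splits]
        raise ValueError(
            f"classes {list(bad)} have fewer cells than the {n_splits} "
            "stratified folds; cannot cross-validate"
        )
    if counts.min() < 10:
        warnings.warn("a class has fewer than 10 cells; estimates may be unstable")
    X = _matrix(ref, features, layer)
    onehot = np.eye(classes.size)[y_idx]

    folds = list(cv_fold_indices(y_idx, n_splits, n_repeats))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga ConvergenceWarning at CV tolerance
        for l1 in l1_grid:
            for alpha in alpha_grid:
                for r, f, tr, te in folds:
                    est = _new_estimator(l1, alpha, cv_max_iter, cv_tol)
                    est.fit(X[tr], y_idx[tr])
                    proba = est.predict_proba(X[te])
                    rows.append(
                        {
                            "l1_ratio": l1,
                            "alpha": alpha,
                            "repeat": r,
                            "fold": f,
                            "mse": weighted_mse(onehot[te], proba),
                        }
                    )
    cv = pd.DataFrame(rows)
    mean_mse = cv.groupby(["l1_ratio", "alpha"], sort=False)["mse"].mean()
    best_l1, best_alpha = mean_mse.index[np.argmin(mean_mse.to_numpy())]

    est = _new_estimator(best_l1, best_alpha, final_max_iter, final_tol)
    est.fit(X, y_idx)
    coef, intercept = est.coef_, est.intercept_
    binary = classes.size == 2 and coef.shape[0] == 1
    return TransferModel(
        classes=classes,
        features=list(features),
        coef=coef,
        intercept=intercept,
        cv_results=cv,
        selected_l1_ratio=float(best_l1),
        selected_alpha=float(best_alpha),
        decision_threshold=decision_threshold,
        binary=binary,
    )


def predict_cells(
    model: TransferModel,
    query: ad.AnnData,
    layer: str = "lognorm",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-cell class probabilities and thresholded labels.

    The argmax class is assigned when its probability reaches the decision
    threshold; otherwise the cell is "unassigned".  Features are aligned
    by name; features missing from the query are zero-filled with a
    warning.
    """
    thr = model.decision_threshold if threshold is None else threshold
    X = _matrix(query, model.features, layer)
    proba = model.predict_proba(X)
    top = proba.argmax(axis=1)
    top_p = proba[np.arange(len(top)), top]
    labels = np.where(top_p >= thr, model.classes[top], UNASSIGNED)
    return pd.DataFrame(
        {"label": labels, "probability": top_p}, index=query.obs_names
    )


def assign_cluster_labels(
    predictions: pd.DataFrame, clusters, std: str = "population"
) -> pd.Series:
    """Cluster-level voting: a cluster inherits the modal projected label
    only if that label's count strictly exceeds mean + 1*std of the
    cluster's per-label counts (population std by default); otherwise the
    cluster is "unresolved".  A modal "unassigned" vote also leaves the
    cluster unresolved."""
    clusters = np.asarray(clusters)
    if clusters.size != len(predictions):
        raise ValueError("clusters must align with predictions")
    ddof = 0 if std == "population" else 1
    out = {}
    for cl in pd.unique(clusters):
        votes = predictions["label"].to_numpy()[clusters == cl]
        if votes.size == 0:
            raise ValueError(f"cluster {cl!r} is empty")
        counts = pd.Series(votes).value_counts()
        threshold = counts.mean() + counts.std(ddof=ddof) if len(counts) > 1 else 0.0
        if len(counts) == 1:
            winner = counts.index[0]
        else:
            winner = counts.index[0] if counts.iloc[0] > threshold else UNRESOLVED
        if winner == UNASSIGNED:
            winner = UNRESOLVED
        out[cl] = winner
    return pd.Series(out, name="cluster_label")


def feature_impact(
    model: TransferModel, method: str = "normal", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-class gene impact table.

    Impact = e^coefficient.  With ``method="normal"`` a normal
    distribution is fitted to the class's coefficients (the log-impacts)
    and each gene's p-value is that normal's survival function at its
    coefficient; ``method="empirical"`` uses the empirical rank survival
    function instead.  Genes with p < ``alpha`` are flagged significant.
    """
    if model.binary:
        coef = np.vstack([-model.coef[0], model.coef[0]])
    else:
        coef = model.coef
    frames = []
    for c, cls in enumerate(model.classes):
        b = coef[c]
        if np.allclose(b, 0.0):
            warnings.warn(f"class {cls!r}: all coefficients zero (fully regularized)")
            p = np.ones_like(b)
        elif method == "normal":
            sd = b.std(ddof=0)
            p = stats.norm.sf(b, loc=b.mean(), scale=sd) if sd > 0 else np.ones_like(b)
        elif method == "empirical":
            ranks = stats.rankdata(b, method="max")
            p = 1.0 - (ranks - 1) / len(b)
        else:
            raise ValueError(f"unknown method {method!r}")
        frames.append(
            pd.DataFrame(
                {
                    "class": cls,
                    "gene": model.features,
                    "coefficient": b,
                    "impact": np.exp(b),
                    "pvalue": p,
                    "significant": p < alpha,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["class", "impact"], ascending=[True, False],
                           ignore_index=True)
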