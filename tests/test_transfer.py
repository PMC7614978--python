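"""Elastic-net label transfer: CV grid, thresholding, voting, impact."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from dropmics import (
    assign_cluster_labels,
    feature_impact,
    predict_cells,
    train_transfer_model,
)
from dropmics.transfer import (
    ALPHA_GRID,
    L1_GRID,
    UNASSIGNED,
    UNRESOLVED,
    TransferModel,
    weighted_mse,
)
from conftest import make_adata


def _labeled_adata(n_per_class=30, n_genes=10, sep=4.0, seed=0, classes=2):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(classes):
        block = rng.normal(0, 1, (n_per_class, n_genes))
        block[:, c] += sep
        X.append(block)
        y += [f"class{c}"] * n_per_class
    adata = make_adata(np.vstack(X), label=y)
    adata.layers["lognorm"] = np.vstack(X)
    return adata


def _fixed_proba_model(probs, n_features=3):
    """TransferModel whose intercepts alone produce the given softmax."""
    probs = np.asarray(probs, float)
    return TransferModel(
        classes=np.array([f"class{i}" for i in range(len(probs))]),
        features=[f"g{j}" for j in range(n_features)],
        coef=np.zeros((len(probs), n_features)),
        intercept=np.log(probs),
        cv_results=pd.DataFrame(),
        selected_l1_ratio=0.0,
        selected_alpha=1.0,
    )


def _query(n_features=3, n_cells=1):
    adata = make_adata(np.zeros((n_cells, n_features)))
    adata.layers["lognorm"] = np.zeros((n_cells, n_features))
    return adata


class TestTraining:
    def test_grid_shape_and_fold_count(self):
        adata = _labeled_adata()
        model = train_transfer_model(adata, "label", features=list(adata.var_names))
        grid = model.cv_results.groupby(["l1_ratio", "alpha"])
        assert len(grid) == 30  # 6 l1_ratio x 5 alpha values
        assert all(len(g) == 15 for _, g in grid)  # 5 splits x 3 repeats
        assert model.selected_l1_ratio in L1_GRID
        assert model.selected_alpha in ALPHA_GRID

    def test_separable_data_near_zero_cv_mse(self):
        adata = _labeled_adata(sep=6.0)
        model = train_transfer_model(adata, "label", features=list(adata.var_names))
        mean = model.cv_results.groupby(["l1_ratio", "alpha"])["mse"].mean()
        dense = mean[[i for i in mean.index if i[0] < 1.0]]
        assert dense.max() < 0.05
        train_pred = predict_cells(model, adata, threshold=0.0)
        assert (train_pred["label"] == adata.obs["label"]).mean() == 1.0

    def test_selected_point_matches_independent_recomputation(self):
        """Exhaustive CV oracle on a small instance: same folds, same fold
        MSEs, same selected grid point."""
        adata = _labeled_adata(n_per_class=15, n_genes=10, sep=1.0, seed=5)
        model = train_transfer_model(adata, "label", features=list(adata.var_names))
        X = adata.layers["lognorm"]
        y = pd.Categorical(adata.obs["label"]).codes
        onehot = np.eye(2)[y]
        rows = []
        for l1 in L1_GRID:
            for alpha in ALPHA_GRID:
                for r in range(3):
                    skf = StratifiedKFold(5, shuffle=True, random_state=r)
                    for f, (tr, te) in enumerate(skf.split(X, y)):
                        est = LogisticRegression(
                            solver="saga", C=alpha,
                            l1_ratio=l1, max_iter=300, tol=1e-3,
                            random_state=0,
                        ).fit(X[tr], y[tr])
                        mse = weighted_mse(onehot[te], est.predict_proba(X[te]))
                        rows.append((l1, alpha, r, f, mse))
        oracle = pd.DataFrame(rows, columns=["l1_ratio", "alpha", "repeat", "fold", "mse"])
        got = model.cv_results.sort_values(["l1_ratio", "alpha", "repeat", "fold"])
        want = oracle.sort_values(["l1_ratio", "alpha", "repeat", "fold"])
        assert np.allclose(got["mse"].to_numpy(), want["mse"].to_numpy(), atol=1e-6)
        best = want.groupby(["l1_ratio", "alpha"])["mse"].mean().idxmin()
        assert (model.selected_l1_ratio, model.selected_alpha) == best

    def test_label_permutation_null(self):
        rng = np.random.default_rng(11)
        adata = _labeled_adata(n_per_class=40, sep=3.0, seed=7)
        perm = adata.copy()
        perm.obs["label"] = rng.permutation(perm.obs["label"].to_numpy())
        half = perm.n_obs // 2
        train, test = perm[:half].copy(), perm[half:].copy()
        model = train_transfer_model(
            train, "label", features=list(perm.var_names),
            l1_grid=(0.5,), alpha_grid=(1.0,), n_repeats=1,
        )
        pred = predict_cells(model, test, threshold=0.0)
        acc = (pred["label"] == test.obs["label"]).mean()
        majority = test.obs["label"].value_counts(normalize=True).max()
        assert acc < majority + 3 * np.sqrt(0.25 / test.n_obs) + 0.05

    def test_small_class_raises(self):
        adata = _labeled_adata(n_per_class=3)
        with pytest.raises(ValueError, match="folds"):
            train_transfer_model(adata, "label", features=list(adata.var_names))


class TestPrediction:
    def test_threshold_examples(self):
        q = _query()
        m1 = _fixed_proba_model([0.95, 0.03, 0.02])
        assert predict_cells(m1, q)["label"].iloc[0] == "class0"
        m2 = _fixed_proba_model([0.60, 0.30, 0.10])
        assert predict_cells(m2, q)["label"].iloc[0] == UNASSIGNED
        m3 = _fixed_proba_model([1 / 3, 1 / 3, 1 / 3])
        assert predict_cells(m3, q)["label"].iloc[0] == UNASSIGNED

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(12)
        model = _fixed_proba_model([0.5, 0.3, 0.2])
        model.coef = rng.normal(0, 1, (3, 3))
        q = _query(n_cells=200)
        q.layers["lognorm"] = rng.normal(0, 2, (200, 3))
        fracs = [
            (predict_cells(model, q, threshold=t)["label"] == UNASSIGNED).mean()
            for t in np.linspace(0.3, 1.0, 8)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_cell_and_feature_order_invariance(self):
        rng = np.random.default_rng(13)
        model = _fixed_proba_model([0.4, 0.6], n_features=4)
        model.coef = rng.normal(0, 1, (2, 4))
        model.binary = False
        q = _query(n_features=4, n_cells=50)
        q.layers["lognorm"] = rng.normal(0, 1, (50, 4))
        base = predict_cells(model, q)
        cell_perm = rng.permutation(50)
        p1 = predict_cells(model, q[cell_perm].copy())
        assert np.allclose(base["probability"].to_numpy()[cell_perm],
                           p1["probability"].to_numpy())
        feat_perm = rng.permutation(4)
        q2 = q[:, feat_perm].copy()
        p2 = predict_cells(model, q2)
        assert np.allclose(base["probability"], p2["probability"])

    def test_missing_features_zero_filled(self):
        model = _fixed_proba_model([0.95, 0.05], n_features=3)
        q = _query(n_features=3)
        q = q[:, [0, 1]].copy()
        with pytest.warns(UserWarning, match="absent"):
            out = predict_cells(model, q)
        assert len(out) == 1


class TestClusterVoting:
    @staticmethod
    def _preds(counts):
        labels, clusters = [], []
        for lab, k in counts.items():
            labels += [lab] * k
            clusters += ["cl"] * k
        return pd.DataFrame({"label": labels, "probability": 1.0}), clusters

    def test_clear_majority(self):
        preds, cl = self._preds({"A": 90, "B": 5, "C": 5})
        assert assign_cluster_labels(preds, cl)["cl"] == "A"

    def test_near_tie_still_resolves(self):
        # mean 33.33, population std ~0.47, threshold ~33.8; A=34 exceeds it
        preds, cl = self._preds({"A": 34, "B": 33, "C": 33})
        assert assign_cluster_labels(preds, cl)["cl"] == "A"

    def test_exact_tie_unresolved(self):
        preds, cl = self._preds({"A": 30, "B": 30})
        assert assign_cluster_labels(preds, cl)["cl"] == UNRESOLVED

    def test_unassigned_majority_unresolved(self):
        preds, cl = self._preds({UNASSIGNED: 95, "A": 5})
        assert assign_cluster_labels(preds, cl)["cl"] == UNRESOLVED

    def test_homogeneous_cluster(self):
        preds, cl = self._preds({"A": 20})
        assert assign_cluster_labels(preds, cl)["cl"] == "A"

    def test_empty_cluster_raises(self):
        preds, cl = self._preds({"A": 3})
        with pytest.raises(ValueError, match="align"):
            assign_cluster_labels(preds, cl + ["cl2"])


class TestFeatureImpact:
    @staticmethod
    def _model(coef):
        coef = np.asarray(coef, float)
        return TransferModel(
            classes=np.array([f"class{i}" for i in range(coef.shape[0])]),
            features=[f"g{j}" for j in range(coef.shape[1])],
            coef=coef,
            intercept=np.zeros(coef.shape[0]),
            cv_results=pd.DataFrame(),
            selected_l1_ratio=0.0,
            selected_alpha=1.0,
        )

    def test_impact_is_exp_coefficient(self):
        table = feature_impact(self._model([[0.0, np.log(2.0), -1.0],
                                            [0.5, 0.0, 0.1]]))
        row = table.set_index(["class", "gene"])
        assert row.loc[("class0", "g0"), "impact"] == pytest.approx(1.0)
        assert row.loc[("class0", "g1"), "impact"] == pytest.approx(2.0)

    def test_outlier_coefficient_is_significant(self):
        rng = np.random.default_rng(14)
        coef = np.vstack([np.r_[rng.normal(0, 0.1, 49), 3.0],
                          rng.normal(0, 0.1, 50)])
        table = feature_impact(self._model(coef))
        sig = table[table["significant"]]
        assert ("class0", "g49") in set(zip(sig["class"], sig["gene"]))

    def test_all_zero_coefficients_warn(self):
        with pytest.warns(UserWarning, match="zero"):
            table = feature_impact(self._model(np.zeros((2, 5))))
        assert not table["significant"].any()

    def test_empirical_sf_option(self):
        coef = np.array([[0.0, 1.0, 2.0, 3.0]])
        table = feature_impact(self._model(np.vstack([coef[0], -coef[0]])),
                               method="empirical")
        c0 = table[table["class"] == "class0"].set_index("gene")
        assert c0.loc["g3", "pvalue"] == pytest.approx(0.25)
        assert c0.loc["g0", "pvalue"] == pytest.approx(1.0)
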