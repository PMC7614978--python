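"""Matrix Market + TSV readers/writers for droplet datasets."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_mtx_dataset(adata: ad.AnnData, outdir, feature_file: str = "genes.tsv") -> None:
    """Write counts as matrix.mtx (cells x features) with cells.tsv and a
    feature table; layers are written as <layer>.mtx alongside."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(adata.X))
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    adata.var.to_csv(outdir / feature_file, sep="\t")
    for name, layer in adata.layers.items():
        spio.mmwrite(outdir / f"{name}.mtx", sparse.coo_matrix(layer))


def read_mtx_dataset(indir, feature_file: str = "genes.tsv") -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx"))
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / feature_file, sep="\t", index_col=0)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    for layer_path in sorted(indir.glob("*.mtx")):
        if layer_path.name == "matrix.mtx":
            continue
        adata.layers[layer_path.stem] = sparse.csr_matrix(spio.mmread(layer_path))
    return adata


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)


def truth_to_dict(truth) -> dict:
    """JSON-serializable view of a SyntheticTruth."""
    return {
        "seed": truth.seed,
        "state_labels": truth.state_labels.tolist(),
        "doublet_flags": truth.doublet_flags.tolist(),
        "empty_flags": None if truth.empty_flags is None else truth.empty_flags.tolist(),
        "marker_genes": truth.marker_genes,
        "signal_protein_of_state": truth.signal_protein_of_state,
        "protein_background_log_mean": truth.protein_background_log_mean,
        "protein_signal_log_mean": truth.protein_signal_log_mean,
        "state_proportions_by_age": np.asarray(truth.state_proportions_by_age).tolist(),
        "age_bins": list(truth.age_bins),
        "sample_gates": None
        if truth.sample_gates is None
        else truth.sample_gates.to_dict(orient="records"),
    }
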