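import anndata as ad
import numpy as np
import pandas as pd
import pytest

from dropmics import SimulationConfig, generate_multiomic_dataset, normalize_lognorm


@pytest.fixture(scope="session")
def small_multiomic():
    cfg = SimulationConfig(
        n_cells=800, n_genes=400, empty_droplet_count=600, seed=0
    )
    return generate_multiomic_dataset(cfg)


@pytest.fixture(scope="session")
def lognormed_rna(small_multiomic):
    rna, _, truth = small_multiomic
    rna = normalize_lognorm(rna.copy())
    rna.obs["state"] = truth.state_labels
    return rna, truth


def make_adata(counts, obs=None, var=None, **obs_cols):
    """Small dense-count AnnData helper for hand fixtures."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    for k, v in obs_cols.items():
        obs[k] = v
    if var is None:
        var = pd.DataFrame(index=[f"g{j}" for j in range(g)])
    return ad.AnnData(X=counts.astype(float), obs=obs, var=var)
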