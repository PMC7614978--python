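"""Synthetic droplet multiomics with planted ground truth.

Generates paired RNA (cell x gene) and ADT (droplet x protein) count
matrices that exhibit the statistical structure the downstream stages
assume: mixtures of cell states with marker-gene enrichment, doublets,
empty droplets carrying only ambient protein counts, per-protein antibody
background on a log scale, CD45+/- FACS sorting with known gate
proportions, and cell-state composition shifting across gestational age
bins.  Every planted parameter is recorded in a :class:`SyntheticTruth`.

RNA counts are negative binomial (gamma-Poisson) with a common per-gene
dispersion; doublets are sums of two cells' expected profiles at doubled
library size; protein counts are Poisson draws around a log-normal
intensity.  One RNG stream per matrix kind (RNA, protein, sorting,
scores) is spawned from the master seed so that, e.g., adding proteins
does not perturb the RNA draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "FacsGateSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_multiomic_dataset",
    "generate_sorted_timeseries",
]

# Per-state doublet-score Beta means are spread over this range, emulating
# cluster-to-cluster variation of ambient doublet scores; doublets draw
# from a high-mean Beta.  Concentrations keep the distributions tight.
_SINGLET_SCORE_RANGE = (0.03, 0.12)
_SINGLET_SCORE_CONC = 100.0
_DOUBLET_SCORE_MEAN = 0.8
_DOUBLET_SCORE_CONC = 20.0


@dataclass(frozen=True)
class FacsGateSpec:
    """Per-sample FACS sorting description.

    pi is the true proportion of the sample's cells inside the positive
    gate, ``s_total`` (S) the total number of sorted cells and ``s_pos``
    (Si for the positive gate) how many of them were taken from the
    positive gate.  ``s_pos / s_total != pi`` induces a known sorting
    bias.
    """

    pi: float
    s_total: int
    s_pos: int

    def validate(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"gate proportion pi must lie in (0, 1), got {self.pi}")
        if self.s_total <= 0:
            raise ValueError("s_total must be positive")
        if not 0 < self.s_pos < self.s_total:
            raise ValueError(
                f"s_pos must lie strictly between 0 and s_total={self.s_total}, got {self.s_pos}"
            )


@dataclass
class SimulationConfig:
    """Planted parameters of the simulated study.

    Defaults emulate a sorted embryonic time course: five gestational age
    bins (post-conception weeks 3, 4, 5, 7 and 8), five cell states with
    ten 5x-weighted marker genes each enriched at ``marker_logfc`` natural
    log-fold change, NB dispersion 0.3, cell library sizes log10-normal
    (3.5, 0.2) and ambient droplets at (2.0, 0.15), and log-normal ADT
    background/signal intensities.
    """

    n_cells: int = 3000
    n_genes: int = 2000
    n_proteins: int = 10
    n_states: int = 5
    n_samples: int = 5
    age_bins: Sequence[float] = (3, 4, 5, 7, 8)
    state_proportions_by_age: np.ndarray | None = None
    marker_logfc: float = 1.0
    n_markers_per_state: int = 8
    marker_weight_range: tuple[float, float] = (5.0, 12.0)
    gene_dispersion: float = 0.3
    doublet_rate: float = 0.05
    empty_droplet_count: int = 5000
    protein_background_mean: float = 1.5
    protein_background_sd: float = 0.3
    protein_signal_mean: float = 3.5
    protein_signal_sd: float = 0.3
    cell_umi_log10_mean: float = 3.5
    cell_umi_log10_sd: float = 0.2
    empty_umi_log10_mean: float = 2.0
    empty_umi_log10_sd: float = 0.15
    facs_gates: Sequence[FacsGateSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_proteins", "n_states", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.empty_droplet_count < 0 or self.n_markers_per_state < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValueError(f"doublet_rate must lie in [0, 1), got {self.doublet_rate}")
        if self.marker_logfc < 0:
            raise ValueError("marker_logfc must be nonnegative")
        if self.state_proportions_by_age is None:
            self.state_proportions_by_age = np.full(
                (len(self.age_bins), self.n_states), 1.0 / self.n_states
            )
        props = np.asarray(self.state_proportions_by_age, dtype=float)
        if props.shape != (len(self.age_bins), self.n_states):
            raise ValueError(
                "state_proportions_by_age must be (n_age_bins, n_states), "
                f"got {props.shape}"
            )
        if np.any(props < 0) or not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every state_proportions_by_age row must be a simplex row")
        self.state_proportions_by_age = props
        if self.facs_gates is not None:
            for g in self.facs_gates:
                g.validate()

    @property
    def state_names(self) -> list[str]:
        return [f"state_{i}" for i in range(self.n_states)]

    def gate_of_state(self, state: int) -> str:
        """States are split between the two sorting gates; the first half
        of the state list is CD45+."""
        return "CD45+" if state < math.ceil(self.n_states / 2) else "CD45-"


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, keyed by the same seed."""

    seed: int
    state_labels: np.ndarray
    doublet_flags: np.ndarray
    empty_flags: np.ndarray | None
    marker_genes: dict[str, list[str]]
    signal_protein_of_state: dict[str, str]
    protein_background_log_mean: float
    protein_signal_log_mean: float
    state_proportions_by_age: np.ndarray
    age_bins: tuple
    sample_gates: pd.DataFrame | None = None
    effective_state_proportions: dict[str, np.ndarray] = field(default_factory=dict)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    kinds = ("rna", "protein", "sorting", "scores")
    children = np.random.SeedSequence(seed).spawn(len(kinds))
    return {k: np.random.default_rng(c) for k, c in zip(kinds, children)}


def _state_profiles(config: SimulationConfig, rng: np.random.Generator):
    """Per-state expected gene proportions with planted marker enrichment."""
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    n_mark = config.n_states * config.n_markers_per_state
    if n_mark > config.n_genes:
        raise ValueError("more marker genes requested than genes available")
    marker_idx = rng.choice(config.n_genes, size=n_mark, replace=False)
    # markers are well-expressed but span a range of base levels so they
    # scatter across mean-expression bins, as real markers do
    lo, hi = config.marker_weight_range
    base[marker_idx] = base.mean() * np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n_mark)
    )
    profiles = np.tile(base, (config.n_states, 1))
    markers: dict[int, np.ndarray] = {}
    for s in range(config.n_states):
        idx = marker_idx[s * config.n_markers_per_state : (s + 1) * config.n_markers_per_state]
        profiles[s, idx] *= math.exp(config.marker_logfc)
        markers[s] = idx
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles, markers


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _draw_rna_counts(rng, config, profiles, states, libsizes) -> np.ndarray:
    counts = np.zeros((len(states), config.n_genes), dtype=np.int32)
    for s in range(config.n_states):
        rows = np.flatnonzero(states == s)
        if rows.size == 0:
            continue
        mean = libsizes[rows, None] * profiles[s][None, :]
        counts[rows] = _nb_counts(rng, mean, config.gene_dispersion)
    return counts


def _doublet_scores(rng, states, doublet, n_states) -> np.ndarray:
    lo, hi = _SINGLET_SCORE_RANGE
    denom = max(n_states - 1, 1)
    means = lo + (hi - lo) * np.arange(n_states) / denom
    m = means[states]
    m[doublet] = _DOUBLET_SCORE_MEAN
    conc = np.where(doublet, _DOUBLET_SCORE_CONC, _SINGLET_SCORE_CONC)
    return rng.beta(m * conc, (1.0 - m) * conc)


def _protein_counts(rng, config, n_droplets, signal_mask) -> np.ndarray:
    """Ambient background for every droplet plus log-normal signal where
    ``signal_mask`` (droplet x protein boolean) is set."""
    bg = rng.poisson(
        np.exp(
            rng.normal(
                config.protein_background_mean,
                config.protein_background_sd,
                size=(n_droplets, config.n_proteins),
            )
        )
    )
    sig = np.zeros_like(bg)
    if signal_mask.any():
        intensity = np.exp(
            rng.normal(
                config.protein_signal_mean,
                config.protein_signal_sd,
                size=int(signal_mask.sum()),
            )
        )
        sig[signal_mask] = rng.poisson(intensity)
    return bg + sig


def generate_multiomic_dataset(config: SimulationConfig):
    """Simulate one multiomic experiment.

    Returns ``(rna, adt, truth)`` where ``rna`` is an AnnData of cell x
    gene counts with QC metadata (sample/lane/age/mito/doublet score and
    a planted clustering), ``adt`` is an AnnData of droplet x protein
    counts (cells first, then ambient-only empty droplets) and ``truth``
    records every planted value.
    """
    rngs = _streams(config.seed)
    rng = rngs["rna"]
    profiles, marker_idx = _state_profiles(config, rng)
    gene_names = [f"g{i:04d}" for i in range(config.n_genes)]

    sample_of_cell = np.arange(config.n_cells) % config.n_samples
    age_of_sample = np.asarray(config.age_bins, dtype=float)[
        np.arange(config.n_samples) % len(config.age_bins)
    ]
    age_row = {a: i for i, a in enumerate(config.age_bins)}
    states = np.empty(config.n_cells, dtype=np.int64)
    for j in range(config.n_samples):
        rows = np.flatnonzero(sample_of_cell == j)
        p = config.state_proportions_by_age[age_row[age_of_sample[j]]]
        states[rows] = rng.choice(config.n_states, size=rows.size, p=p)

    libsizes = 10.0 ** rng.normal(
        config.cell_umi_log10_mean, config.cell_umi_log10_sd, config.n_cells
    )
    n_doub = int(round(config.doublet_rate * config.n_cells))
    doublet = np.zeros(config.n_cells, dtype=bool)
    partner_state = states.copy()
    if n_doub > 0:
        doub_idx = rng.choice(config.n_cells, size=n_doub, replace=False)
        doublet[doub_idx] = True
        partner_state[doub_idx] = states[rng.integers(0, config.n_cells, size=n_doub)]

    counts = _draw_rna_counts(rng, config, profiles, states, libsizes)
    if n_doub > 0:
        # doublet = sum of the two partners' expected profiles at doubled
        # library size (each partner contributes its own full library)
        rows = np.flatnonzero(doublet)
        mean = libsizes[rows, None] * (
            profiles[states[rows]] + profiles[partner_state[rows]]
        )
        counts[rows] = _nb_counts(rng, mean, config.gene_dispersion)

    scores = _doublet_scores(rngs["scores"], states, doublet, config.n_states)
    pct_mito = rngs["scores"].beta(2.5, 47.5, size=config.n_cells)

    state_names = config.state_names
    cluster = np.where(doublet, "doublet", np.asarray(state_names)[states])
    obs = pd.DataFrame(
        {
            "sample_id": pd.Categorical([f"S{j}" for j in sample_of_cell]),
            "donor_id": pd.Categorical([f"D{j}" for j in sample_of_cell]),
            "lane_id": pd.Categorical([f"L{j}" for j in sample_of_cell]),
            "age_pcw": age_of_sample[sample_of_cell],
            "facs_gate": pd.Categorical(
                [config.gate_of_state(s) for s in states]
            ),
            "pct_mito": pct_mito,
            "doublet_score": scores,
            "cluster_id": pd.Categorical(cluster),
        },
        index=[f"cell{i:05d}" for i in range(config.n_cells)],
    )
    rna = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=gene_names),
    )

    # --- protein assay: cells first, then ambient-only empty droplets ---
    n_droplets = config.n_cells + config.empty_droplet_count
    signal_mask = np.zeros((n_droplets, config.n_proteins), dtype=bool)
    sig_protein = np.asarray([s % config.n_proteins for s in range(config.n_states)])
    cell_rows = np.arange(config.n_cells)
    signal_mask[cell_rows, sig_protein[states]] = True
    signal_mask[cell_rows[doublet], sig_protein[partner_state[doublet]]] = True
    adt_counts = _protein_counts(rngs["protein"], config, n_droplets, signal_mask)

    empty_umi = 10.0 ** rngs["protein"].normal(
        config.empty_umi_log10_mean,
        config.empty_umi_log10_sd,
        config.empty_droplet_count,
    )
    total_rna_umi = np.concatenate(
        [np.asarray(counts.sum(axis=1)).ravel(), empty_umi]
    )
    empty_flags = np.arange(n_droplets) >= config.n_cells
    adt_obs = pd.DataFrame(
        {
            "barcode": [f"bc{i:06d}" for i in range(n_droplets)],
            "total_rna_umi": total_rna_umi,
            "droplet_class": pd.Categorical(
                ["unknown"] * n_droplets, categories=["cell", "empty", "unknown"]
            ),
        },
        index=[f"drop{i:06d}" for i in range(n_droplets)],
    )
    adt = ad.AnnData(
        X=sparse.csr_matrix(adt_counts),
        obs=adt_obs,
        var=pd.DataFrame(index=[f"prot{p:02d}" for p in range(config.n_proteins)]),
    )

    truth = SyntheticTruth(
        seed=config.seed,
        state_labels=np.asarray(state_names)[states],
        doublet_flags=doublet,
        empty_flags=empty_flags,
        marker_genes={
            state_names[s]: [gene_names[g] for g in marker_idx[s]]
            for s in range(config.n_states)
        },
        signal_protein_of_state={
            state_names[s]: f"prot{sig_protein[s]:02d}" for s in range(config.n_states)
        },
        protein_background_log_mean=config.protein_background_mean,
        protein_signal_log_mean=config.protein_signal_mean,
        state_proportions_by_age=config.state_proportions_by_age,
        age_bins=tuple(config.age_bins),
    )
    return rna, adt, truth


def generate_sorted_timeseries(config: SimulationConfig):
    """Simulate a FACS-sorted time course: one AnnData per sample.

    Each sample ``j`` has age ``age_bins[j % n_ages]`` and the sorting
    description ``config.facs_gates[j]``: ``s_pos`` cells are drawn from
    the CD45+ gate and ``s_total - s_pos`` from the CD45- gate, while the
    true (unsorted) gate split is ``pi``.  Within a gate, states follow
    the age bin's proportions row restricted to that gate's states and
    renormalized, so the true unsorted composition of a sample is
    ``pi * q_pos`` / ``(1 - pi) * q_neg``.  A latent embedding
    (``obsm["X_latent"]``, state centroids + isotropic noise) is attached
    for graph construction downstream.

    Returns ``(samples, truth)``; ``truth.sample_gates`` holds one row
    per (sample, gate) with pi, S and Si for the FACS correction.
    """
    if config.facs_gates is None:
        raise ValueError("generate_sorted_timeseries requires config.facs_gates")
    if len(config.facs_gates) != config.n_samples:
        raise ValueError("facs_gates must supply one spec per sample")

    rngs = _streams(config.seed)
    profiles, marker_idx = _state_profiles(config, rngs["rna"])
    gene_names = [f"g{i:04d}" for i in range(config.n_genes)]
    state_names = np.asarray(config.state_names)
    gates = np.asarray([config.gate_of_state(s) for s in range(config.n_states)])
    pos_states = np.flatnonzero(gates == "CD45+")
    neg_states = np.flatnonzero(gates == "CD45-")
    if pos_states.size == 0 or neg_states.size == 0:
        raise ValueError("both gates need at least one state")

    sort_rng = rngs["sorting"]
    samples: list[ad.AnnData] = []
    gate_rows = []
    all_states: list[np.ndarray] = []
    truth_props: dict[str, np.ndarray] = {}
    for j, gate in enumerate(config.facs_gates):
        age = float(config.age_bins[j % len(config.age_bins)])
        p = config.state_proportions_by_age[list(config.age_bins).index(age)]
        q_pos = p[pos_states] / p[pos_states].sum()
        q_neg = p[neg_states] / p[neg_states].sum()
        n_neg = gate.s_total - gate.s_pos
        states = np.concatenate(
            [
                pos_states[sort_rng.choice(pos_states.size, gate.s_pos, p=q_pos)],
                neg_states[sort_rng.choice(neg_states.size, n_neg, p=q_neg)],
            ]
        )
        sort_rng.shuffle(states)
        eff = np.zeros(config.n_states)
        eff[pos_states] = gate.pi * q_pos
        eff[neg_states] = (1.0 - gate.pi) * q_neg
        sample_id = f"S{j}"
        truth_props[sample_id] = eff

        libsizes = 10.0 ** rngs["rna"].normal(
            config.cell_umi_log10_mean, config.cell_umi_log10_sd, states.size
        )
        counts = _draw_rna_counts(rngs["rna"], config, profiles, states, libsizes)
        latent = 3.0 * np.eye(config.n_states)[states] + sort_rng.normal(
            0.0, 0.7, size=(states.size, config.n_states)
        )
        obs = pd.DataFrame(
            {
                "sample_id": sample_id,
                "donor_id": f"D{j}",
                "lane_id": f"L{j}",
                "age_pcw": age,
                "facs_gate": pd.Categorical(gates[states], categories=["CD45+", "CD45-"]),
                "cell_label": state_names[states],
            },
            index=[f"{sample_id}_cell{i:05d}" for i in range(states.size)],
        )
        adata = ad.AnnData(
            X=sparse.csr_matrix(counts),
            obs=obs,
            var=pd.DataFrame(index=gene_names),
        )
        adata.obsm["X_latent"] = latent
        samples.append(adata)
        all_states.append(states)
        gate_rows.append(
            {"sample_id": sample_id, "gate": "CD45+", "pi": gate.pi,
             "S": gate.s_total, "Si": gate.s_pos, "age_pcw": age}
        )
        gate_rows.append(
            {"sample_id": sample_id, "gate": "CD45-", "pi": 1.0 - gate.pi,
             "S": gate.s_total, "Si": n_neg, "age_pcw": age}
        )

    states_cat = np.concatenate(all_states)
    truth = SyntheticTruth(
        seed=config.seed,
        state_labels=state_names[states_cat],
        doublet_flags=np.zeros(states_cat.size, dtype=bool),
        empty_flags=None,
        marker_genes={
            config.state_names[s]: [gene_names[g] for g in marker_idx[s]]
            for s in range(config.n_states)
        },
        signal_protein_of_state={},
        protein_background_log_mean=config.protein_background_mean,
        protein_signal_log_mean=config.protein_signal_mean,
        state_proportions_by_age=config.state_proportions_by_age,
        age_bins=tuple(config.age_bins),
        sample_gates=pd.DataFrame(gate_rows),
        effective_state_proportions=truth_props,
    )
    return samples, truth
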