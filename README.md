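# dropmics

Droplet multiomic QC and analysis for sorted single-cell time courses:
CITE-seq antibody-background normalization, probabilistic cell-state
label transfer, FACS-corrected neighborhood differential abundance, and
gene-module enrichment tracking — together with a synthetic-data
generator that plants known ground truth for every one of those stages.

The package is aimed at computational biologists analyzing droplet
scRNA-seq/CITE-seq experiments in which cells were FACS-isolated through
known gates (e.g. CD45+/CD45−) across a developmental time course, and
at method developers who need a reproducible, truth-bearing testbed for
such pipelines.

## What it implements

**Quality control** (`dropmics.qc`)

- Strict cell/gene filters (total UMIs < 2000, genes < 200,
  mitochondrial fraction > 20%, genes in < 3 cells).
- Per-lane doublet-cluster purge: a cluster is removed when its median
  doublet score exceeds median(cluster medians) + 1.48·MAD, with the MAD
  unscaled.
- Total-count normalization to 10⁴ per cell with ln(1+x) transform,
  dispersion-based HVG selection in 20 equal-frequency mean bins, and
  one-vs-rest Wilcoxon marker testing (genes expressed in > 25% of the
  group, |logFC| ≥ 0.25, Benjamini–Hochberg across tested genes).
- Partition benchmarking: AMI, ARI, silhouette, within-cluster SS.

**CITE-seq background chain** (`dropmics.citeseq`), in fixed order:

1. Empty-droplet discovery on the log₁₀ total-UMI histogram at
   round(3.322·log₁₀ X) bins, peak sweep over prominences 0–20 ×
   widths 0–10, with a mean − 1.96·sd fallback.
2. DSB normalization: per protein, z-score log1p counts against the
   ambient (empty-droplet) distribution.
3. Gaussian-mixture background model over cells in protein space,
   k = 2…21, selected by BIC; per protein, μ_bg is the smallest
   component mean.
4. Per-cell background score mean_p exp(μ_bg,p − x_c,p), min–max scaled
   to [0, 1].
5. Per-protein Gaussian linear regression of the DSB value on the
   background score; the corrected layer keeps residuals + intercept.

**Label transfer** (`dropmics.transfer`): multinomial elastic-net
logistic regression tuned on the grid l1_ratio ∈ {0, 0.2, 0.4, 0.6,
0.8, 1} × α ∈ {0.2, 0.4, 0.6, 0.8, 1} (α = inverse regularization
strength) with 5 stratified splits × 3 repeats, scored by the weighted
MSE between one-hot labels and predicted probabilities.  Cells are
assigned at a 0.9 probability threshold; clusters inherit the modal
label only beyond mean + 1·std of the label counts; per-gene impact is
e^coefficient with significance from the survival function of a normal
fitted to each class's coefficients.

**Differential abundance** (`dropmics.abundance`): KNN neighborhoods
(index cells sampled at prop = 0.05), per-sample counts modeled as a
negative-binomial GLM on gestational age with offset
log(N_s) − f_s, where f_s = log(π_i·S/S_i) is the FACS isolation
correction for a sample sorted through gate *i* (π_i true gate
proportion, S_i/S sorted fraction); spatial FDR via weighted
Benjamini–Hochberg with weights 1/k-distance; neighborhood labels by
>50% majority vote.

**Module tracking** (`dropmics.modules`): gene-module scores against 200
control genes sampled from 50 expression bins, enriched-cell (score > 0)
proportion series across age bins with per-gene >0-expression
eligibility, and robust (median/MAD) standardization.

**Synthetic data** (`dropmics.simulate`): negative-binomial RNA counts
with per-state marker enrichment, doublets as summed profiles, ambient
protein background (log-normal, Poisson-rounded), empty droplets, and
FACS-sorted time series with configurable gate proportions and sorted
fractions — all planted parameters recorded in a `SyntheticTruth`.

## Worked example

```python
import dropmics as dm

cfg = dm.SimulationConfig(n_cells=3000, n_genes=300,
                          empty_droplet_count=5000, seed=7)
rna, adt, truth = dm.generate_multiomic_dataset(cfg)

part = dm.detect_empty_droplets(adt.obs["total_rna_umi"].to_numpy())
print(part.n_bins, part.fallback, int(part.empty_mask.sum()))

adt = dm.dsb_normalize(adt, part)
model = dm.fit_background_gmm(adt, k_max=8)
print(model.selected_k, model.mu_bg.round(2))
```

prints

```
13 False 5000
8 [-0.23 -0.19 -0.24 -0.28 -0.11 -0.17 -0.23 -0.14 -0.25 -0.37]
```

The histogram of 8000 droplets gets 13 bins (round(3.322·log₁₀ 8000));
the ambient peak is found without the fallback, and all 5000 planted
empty droplets fall under it.  The mixture model then selects the
largest k in the searched range (discretized count data rewards extra
components, so BIC is still falling at the cap) and reports each
protein's background component mean on the DSB z-score scale: about
−0.2, i.e. at the ambient level, which is zero by construction after
DSB — the planted value is recovered.

`dropmics.pipeline.run_pipeline(outdir, seed=0)` chains every stage
(simulate → QC → CITE-seq normalization → label transfer → differential
abundance → module tracking) and serializes each stage report to JSON or
TSV under `outdir`.  A thin CLI exposes the same: `dropmics simulate`
and `dropmics pipeline`.

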