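# Methods

This note documents the models and procedures implemented in `dropmics`,
the assumptions behind them, the defaults of the synthetic-data
generator, and the numerical choices made where the design was open.

## Synthetic droplet data

The generator emulates a FACS-sorted droplet multiomic experiment over
five gestational age bins (3, 4, 5, 7 and 8 post-conception weeks).

**RNA counts.** Each of `n_states` cell states has an expected gene
profile built from a shared log-normal(0, 1) gene weight vector; each
state's `n_markers_per_state` (default 8) marker genes are multiplied by
`exp(marker_logfc)` (default e¹).  Marker base weights are drawn
log-uniformly between 5× and 12× the mean gene weight so that markers
are well-expressed yet scatter across mean-expression bins, as real
marker genes do.  Counts are gamma–Poisson (negative binomial) with a
common dispersion of 0.3 (Var = μ + 0.3μ²), typical of droplet UMI
data.  Library sizes are log₁₀-normal(3.5, 0.2).  With these defaults a
state's markers exceed other states' mean log-normalized expression by
the planted log-fold change to within a few percent (the ln(1+x)
transform and profile renormalization each shave a little; the contract
is verified to ±0.1 in the tests).

**Doublets.** A fraction `doublet_rate` (default 5%) of cells are
doublets: their expected profile is the sum of two cells' profiles, i.e.
a doubled library.  Because doublet *detection* is upstream of this
package, doublet scores are planted directly: per-state Beta
distributions with means spread over 0.03–0.12 (concentration 100) for
singlet clusters — real per-cluster score levels differ — and
Beta(mean 0.8, concentration 20) for the doublet cluster.  The spread of
the singlet cluster levels is what gives the median + 1.48·MAD rule its
operating margin; if all clusters shared one score distribution the MAD
of cluster medians would collapse to sampling noise and the rule would
remove clusters essentially at random.

**Proteins.** Every droplet draws an ambient count per protein as
Poisson(exp(N(1.5, 0.3))) (log-normal intensity, Poisson-rounded to
integer counts).  Each state has one signal protein, adding
Poisson(exp(N(3.5, 0.3))).  Empty droplets (`empty_droplet_count`,
default 5000) carry ambient protein counts only, with total RNA UMIs
log₁₀-normal(2.0, 0.15) against the cells' (3.5, 0.2) — a bimodal
droplet population.

**Sorting.** In the sorted time series each sample has a true positive-
gate proportion π and sorted counts S (total) and S_i (from the gate).
The first half of the state list is CD45+; within a gate, states follow
the age bin's proportions row renormalized to that gate.  Setting
S_i/S ≠ π plants a known sorting bias.  A latent embedding (state
centroids at distance 3 with isotropic sd 0.7) is attached for graph
construction; it stands in for an integrated expression embedding.

**Determinism.** One RNG stream per matrix kind (RNA, protein, sorting,
scores) is spawned from the master seed, so outputs are bit-identical
across runs and adding one modality never perturbs another.

**What the generator does not emulate** — ambient RNA contamination,
batch effects, read-level noise, cell-cycle structure, isotype controls,
or genotype mixtures.  Passing tests therefore demonstrate that each
procedure recovers what it is designed to recover under its own model
assumptions, not that those assumptions hold on any particular real
dataset.

## QC rules

Cell filters are strict inequalities (a cell with exactly 2000 UMIs,
200 genes and 20% mitochondrial reads is retained), "reads" meaning
total UMI counts.  Gene filtering (expressed in ≥ 3 remaining cells)
runs after cell filtering and is not iterated.  The doublet-cluster rule
operates per sequencing lane on cluster medians of the doublet score;
the MAD is unscaled because the 1.48 multiplier is written explicitly
into the threshold.  A lane with a single cluster is left untouched —
the rule compares clusters and is undefined there — and flagged in the
QC report.  Clustering itself is consumed as input labels.

HVG selection bins genes into 20 equal-frequency mean bins (bin count
not dictated by the procedure's definition; equal-frequency keeps tail
bins populated) and z-scores the var/mean dispersion within bins, then
ranks genes with mean inside (0.001, 10).  A known limitation, shared
with the standard implementations: when high variance is confounded with
high mean (as for strongly expressed markers under NB noise), per-bin
z-scoring cannot cleanly isolate the planted genes; the label-transfer
workflow therefore accepts caller-supplied features and the recommended
practice is reference-supervised marker ranking (see below).

Marker testing gates genes on > 25% expression within the group before
testing (Mann–Whitney U, two-sided, asymptotic with tie correction) and
applies Benjamini–Hochberg across exactly the tested genes of each
group; reported rows additionally satisfy |logFC| ≥ 0.25, where logFC is
the difference of mean log-normalized expression.

## CITE-seq background chain

The stages run in a fixed order, each reading only layers the previous
ones wrote.

**Empty-droplet detection.** The histogram of log₁₀(1 + total UMI) uses
round(3.322·log₁₀ X) bins — 3.322 ≈ 1/log₁₀ 2 makes this Sturges-like;
a natural-log reading would give an implausibly small handful of bins.
Peaks are collected over a sweep of integer prominences 0–20 crossed
with widths 0–10.  A peak qualifies as the ambient peak when its
position (on the log₁₀-UMI axis, compared against statistics on the same
axis) lies below mean − 1.96·sd; that cut is only reachable when ambient
droplets are a small minority (below ~21% of droplets the low mode can
sit 1.96σ under the mixture mean; above that it cannot), so when it
qualifies nothing and at least two peaks exist, the tallest peak
strictly below the mean is taken instead.  Droplets at or below the
histogram valley between the ambient peak and the next peak to its right
are classed empty; the valley is the natural boundary of "droplets under
the peak" (a half-width boundary clips the ambient mode's upper tail).
With no usable peak, the fallback classes droplets below
mean − 1.96·sd as empty and sets a flag.

**DSB.** Per protein, log1p counts are centred and scaled by the ambient
(empty-droplet) mean and standard deviation; ambient droplets are
exactly unit z-scores afterwards, and a cell's value is its distance
from ambient in ambient SD units.  Zero ambient variance is floored at
1e-8 with a warning.

**Background mixture.** Diagonal-covariance Gaussian mixtures over cells
in protein (DSB) space, k = 2…21, 5 initializations, fixed seed; k is
chosen by BIC, with AIC recorded and disagreements noted (BIC is the
consistency-preferring criterion and is listed first).  Both criteria
are computed in the standard orientation (−2L + penalty, minimized).
Per protein, μ_bg is the smallest component mean of the selected model.
A univariate per-protein variant is available behind `per_protein=True`.
Two caveats are inherent: with k forced ≥ 2, data that are truly one
Gaussian get split, displacing the lowest component mean ~0.5–0.7 sd
below the global mean; and on discretized count-derived values BIC often
keeps improving up to the cap, where the smallest-mean component still
tracks the ambient level.

**Background score and regression.** The per-cell score is the mean over
proteins of exp(μ_bg − x) (median optional; the aggregation across
proteins is a choice — the ratio is defined per protein but consumed per
cell), min–max scaled to [0, 1] as (r − min)/(max − min) — the plain
min–max form, which actually attains 1.  Scores order inversely with
expression.  Each protein's DSB values are then regressed on the score
by ordinary least squares and replaced with residuals + intercept:
the background-associated component is removed, the location kept, and
by least-squares orthogonality the corrected values have exactly zero
sample covariance with the score.

## Label transfer

The classifier is a multinomial logistic regression with elastic-net
penalty (saga solver, fixed seed).  The grid is all six printed l1_ratio
values {0, 0.2, 0.4, 0.6, 0.8, 1} — pure ridge and pure lasso are legal
ends — crossed with α ∈ {0.2, 0.4, 0.6, 0.8, 1} acting literally as the
inverse of the regularization strength (larger α = weaker penalty).
Selection uses 5 stratified splits × 3 repeats (repeat r seeds the
shuffle with r); the fold score is the MSE between one-hot labels and
predicted probabilities, class-frequency weighted within the fold, and
the winner minimizes the unweighted mean of the 15 fold scores, ties
resolved in grid order.  CV fits use a selection-grade tolerance
(max_iter 300, tol 1e-3 by default); the winning point is refitted on
all data at 2000/1e-4.  Probabilities (not hard labels) enter the MSE;
a hard-label variant sits behind `weighted_mse` if needed.

Features are whatever the caller supplies (the natural inputs being
HVGs, a low-dimensional representation, or reference-supervised marker
genes).  On NB-noise synthetic data the recommended and benchmarked
choice is the union of the reference's Wilcoxon marker genes with a set
of HVG "null" features; the nulls anchor the coefficient distribution
that the impact significance test fits.

Cells are assigned the argmax class when its probability is ≥ 0.9, else
"unassigned"; raising the threshold can only grow the unassigned set.
Cluster voting uses the population standard deviation over the cluster's
per-label counts (the rule is a population description, not an
inference) and requires the modal count to strictly exceed mean + std;
ties and modal-unassigned clusters are "unresolved".  Impact scores are
e^coefficient per feature; per class, a normal is fitted to the
coefficients and each feature's p-value is the fitted survival function
at its coefficient (an empirical-rank survival function is available),
significant at p < 0.05.

## Neighborhood differential abundance

Neighborhoods are index cells (sampled without replacement at
prop = 0.05 of cells, seeded) plus their KNN-graph neighbors; the
per-neighborhood × sample count matrix and each index cell's k-distance
(largest stored neighbor distance) are tabulated.  Per neighborhood,
counts across samples follow a negative-binomial GLM with log link on
gestational age treated as a continuous covariate in weeks — the five
age bins span 3–8 PCW and a single slope provides the signed
fold-change the analysis reports.  A common NB dispersion is estimated
by method of moments pooled over neighborhoods from Poisson fits
(α = Σ[(y−μ)² − μ]/Σμ², floored at 1e-8), then each neighborhood is
refitted and the age coefficient tested two-sided by Wald (LRT behind a
flag).

**FACS correction.** For a sample sorted through gate *i*,
f_s = log(π_i·S/S_i) (natural log; exactly 0 under unbiased sorting).
A gate sorted at fraction S_i/S when its true share is π_i multiplies
that gate's expected neighborhood counts by S_i/(π_i·S) = exp(−f_s), so
the model offset that absorbs the bias is log(N_s) − f_s, applied
per neighborhood through the (sample, gate) of the neighborhood's cells.
With f_s = 0 everywhere this reduces exactly to the uncorrected model.
Note that a bias identical across all samples is absorbed by the
intercept and harms nothing; the correction matters when sorting depth
co-varies with the design covariate, which is the scenario the
calibration study simulates (π = 0.8 everywhere, sorted fraction
0.2–0.6 across age bins).

**Spatial FDR.** P-values receive a weighted Benjamini–Hochberg step-up
with weights 1/k-distance (neighborhoods in dense regions, which overlap
more, weigh less); with equal weights the procedure reduces exactly to
classical BH.  One weighted correction is applied (no second weighting
scheme).  Neighborhood labels are the >50% majority member label, else
"Mixed".

## Module tracking

A module score is mean(module gene expression) − mean(control gene
expression) per cell, on the log-normalized layer.  Genes are cut into
50 equal-frequency bins by mean expression (ties broken by stable name
order); for each module gene, up to 200 controls are sampled from its
bin, excluding the module genes themselves (self-controls deflate the
score; an `exclude_module_genes=False` switch exists, under which a
module that is its own control set scores exactly 0).  Scores are
deterministic under a fixed seed and invariant to gene column order and
to global constant shifts.  A cell is enriched when its score is
strictly positive; enriched proportions are reported per age bin over
eligible cells (for single-gene tracking, cells with > 0 log-normalized
counts of the gene), with enriched counts carried so plots can hide or
size symbols below a display threshold (e.g. 500 cells) without touching
the statistics.  Robust standardization is (x − median)/MAD with the MAD
unscaled, and refuses inputs whose MAD is zero.

## Problem sizes

The simulation studies run at desk scale, chosen to keep each study
under a few minutes on one CPU while leaving clear statistical margins:
3000-cell multiomic datasets with 2000 genes (300 for protein-focused
studies), 5000 empty droplets, 100 repeated simulations for the
doublet-rule study, a 10 050-cell/15-sample sorted time series giving
~500 neighborhoods for the calibration and power studies (graph k = 30
for calibration; k = 100 for power, where per-neighborhood counts set
the detectable effect), and a 3000-cell label-transfer benchmark
(1000 reference / 2000 query, ~190 features).

## Known limitations

- The empty-droplet peak qualification departs from a literal
  mean − 1.96·sd cut when ambient droplets dominate (see above); the
  fallback path retains the literal rule.
- The NB-GLM uses a single pooled dispersion and Wald tests; with few
  samples the test is mildly anti-conservative, which the calibration
  study bounds empirically.
- Impact significance assumes the class's coefficients are roughly
  normal with sparse strong effects; heavily regularized models (all
  coefficients zero) yield an empty significant set with a warning.
- The generator's latent embedding makes neighborhoods nearly
  state-pure; real embeddings mix states at boundaries, which weakens
  majority labels and dilutes per-neighborhood effects.
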