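# Methods

## Problem setting

The classifier consumes one symmetric functional-connectivity (FC) matrix
per subject — region-by-region Pearson correlations of resting-state fMRI
time series, unit diagonal, values in [−1, 1] — plus a binary diagnosis
label, and predicts the label. Both hypo- and hyper-connectivity are
informative in neurodevelopmental disorders, and positive and negative
correlations carry distinct physiology, so the model never mixes signs:
each connectome becomes a positive and a negative nonnegative graph, and
every processing branch is duplicated across signs.

## View construction

**Signed split.** `pos = max(C, 0)`, `neg = max(−C, 0)` on the
off-diagonal; `pos − neg + I` reconstructs `C` exactly. Diagonals are
zero; attention neighborhoods always include the node itself so the
softmax is defined even for isolated nodes.

**Views as graded sparsifications.** A "view" is the signed graph
thresholded to its top `⌈ρ_v · P⌉` largest-magnitude edges, where `P`
counts the strictly positive upper-triangle candidates of that sign and
edges are mirrored symmetrically. Retention fractions are strictly
increasing (defaults: evenly spaced over [0.2, 0.8]; three views), so the
views form a nested family from a sparse skeleton of the strongest
connections to a dense graph — the multi-view convention of the
multi-view GCN/GAT literature this design sits in. Ties in the top-k cut
are broken by (weight desc, smaller node index, larger node index) for
cross-platform determinism.

**Node features.** Defaults to the node's row of the signed FC half
(width F = N): it is the only per-node information the matrix provides.
`degree` and `identity` modes exist for experiments. A consequence worth
stating plainly: fc-row features are region-indexed, so the model is
invariant to reordering the *node list* (each node keeping its descriptor
vector) but not to re-expressing the feature coordinates themselves —
subjects must share a parcellation, which is also true of every linear
layer whose width is N.

## Architecture

Per (view, sign) channel: GAT-1 (ELU output) → residual addition with a
learned linear projection of the raw features (needed because feature
width N generally differs from the 64-wide GAT output; identity when they
match) → GAT-2 (linear output). Attention is the canonical single-layer
scorer `LeakyReLU(aᵀ[Wh_i ‖ Wh_j])` with slope 0.2, masked to first-order
neighbors; edge weights mask only — scores are feature-driven. One head
by default (head count configurable).

Per view: the mean-pooled GAT-2 outputs of both signs concatenate to a
128-vector feeding an auxiliary Linear(128,16)→ReLU→Linear(16,2) head.
Each sign's GAT-2 tokens are lifted 64→96 by a linear projection and
passed through one pre-norm transformer encoder block (4 heads,
feed-forward width 2d, no positional encoding — brain regions are
unordered, and relabeling invariance depends on it).

Cross-view fusion: the cross-attention block LayerNorms both inputs
with a shared first norm, cross-attends (queries from the fold state,
keys *and* values from the next view — keys must travel with values for
the attention output to be a well-defined convex mixture when token
counts differ), adds the result to the fold state, then adds an MLP of
the re-normalized sum. Blocks are left-folded over the views separately
per sign; self-attention (the encoder block) is the same block with both
inputs equal. Fold steps do not share parameters. The last two fold
outputs per branch (the lone encoder output for V = 1; the single fold
output used twice for V = 2, keeping the head width stable) are
mean-pooled over tokens and concatenated — 4 × 96 = 384 by default — into
Linear(384,32)→ReLU→Linear(32,16)→ReLU→Linear(16,2).

Mean pooling is used for every graph readout: it is permutation-invariant
and makes the head width independent of graph size. Flattening raw S×d
token matrices instead would tie the head to N and break the 384
bookkeeping; pooling is the reconciliation that keeps both printed head
widths (128 per view, 384 fused) exact simultaneously with the 64→96
encoder lift.

**Width bookkeeping caveat.** The two head widths cannot both hold at a
single constant token width: 128 = 2 × 64 fixes the GAT output at 64,
while 384 = 4 × 96 fixes the encoder width at 96. The 64→96 input
projection of the encoder stage is the explicit bridge.

## Loss and prediction

`L = CE(fusion logits, y) + λ Σ_v CE(view_v logits, y)` with λ = 0.5.
The per-view heads act as deep supervision: they give each branch its own
gradient path and regularize the shared trunk. Prediction uses the fusion
head only (argmax; probabilities via softmax, threshold 0.5 for counts).

## Implementation substrate

All layers run on a small in-repo reverse-mode autodiff engine over
float64 numpy arrays (tape of primitive ops with broadcasting-aware
backward closures). This was a deliberate choice: the model is small
(~0.85 M parameters at defaults), runs on CPU, gains determinism from
single-threaded float64 numpy, and the engine makes the finite-difference
gradient verification (below) a first-class diagnostic. Batching stacks
subjects on a leading axis, so a training step is a few hundred large
numpy ops rather than per-subject Python loops.

Initialisation is uniform Glorot from one seeded generator per model;
config + seed pins every weight. Optimization is Adam (lr 1e-3, weight
decay 5e-4 added to the gradient, β = (0.9, 0.999)); the RunConfig
default is 100 epochs at batch 16. Dropout (default 0) can be applied to
encoder inputs and fused features during training.

## Synthetic cohorts

Subjects are drawn as `T` multivariate-Gaussian timepoints from a modular
block covariance, then reduced to the sample Pearson correlation — the
same estimator applied to real rs-fMRI. Defaults: N = 32 regions in four
modules of 8, T = 200 timepoints, 50 subjects per class, within-module
correlation 0.6. The class effect is hypo-connectivity: the designated
module-1/module-2 block has correlation 0.4 in controls and 0.4 − δ in
class 1 (δ = 0.3 by default; the `cross_corr` baseline is a config
field). The module-3/module-4 block is anti-correlated at −0.2 so the
negative-sign branch sees genuine edges. Subject-level jitter
(sd 0.03) perturbs the three block levels, with positive-semidefiniteness
re-checked (up to 10 redraws). Per-subject seeds derive deterministically
from (cohort seed, class, index) and are recorded in the manifest.

What the generator does *not* emulate: hemodynamics, site/scanner
effects, motion, global-signal artifacts, heterogeneous effect loci.
Passing synthetic benchmarks therefore shows the architecture can extract
clean modular group differences end to end — not that it attains any
particular accuracy on real multi-site cohorts.

## Evaluation protocol

Stratified k-fold (k = 5) with per-fold training from scratch; fold
assignment, per-fold model seeds and shuffling all derive from the run
seed, so repeated runs are bitwise identical. Metrics: confusion counts,
accuracy, sensitivity (recall of the positive/diagnosed class),
specificity, and AUC as the Mann–Whitney rank statistic (ties ½;
undefined and reported as NaN for single-class sets). The metric
identities are recomputed and asserted on every report.

The shipped synthetic experiments (tests and `scripts/acceptance.py`) use
100 subjects, N = 32, and 25 training epochs per fold — the scale at
which the planted-effect benchmarks are run and reported.

## Numerical choices and diagnostics

- float64 everywhere; attention masking via additive −1e30 fill before
  softmax, then exact zeroing off-neighborhood.
- LayerNorm uses population variance and ε = 1e-5.
- Gradient check: central differences (ε = 1e-6) on a 5-node toy model
  probe entries of every parameter group; max relative error is ~1e-9,
  asserted < 1e-4.
- Degenerate inputs: empty sign channels degrade to self-loop-only graphs
  with a warning; single-class evaluation reports NaN AUC with counts.

## Known limitations

- The coarsening hook (`MVGATModel.coarsen`) is an extension point only;
  no graph-coarsening procedure ships.
- Views differ only by edge density; other multi-view constructions
  (atlases, frequency bands) would slot into `ViewConfig` but are not
  implemented.
- fc-row features assume a shared parcellation across subjects (see View
  construction).
- No harmonization for multi-site data; ingestion starts at the matrix
  level (no preprocessing of 4D fMRI).
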