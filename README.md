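# mvgat

Multi-view signed graph attention with cross-view transformer fusion for
classifying functional connectomes — for example distinguishing autism
spectrum disorder (ASD) from typical controls from resting-state fMRI
correlation matrices.

## Who this is for

Researchers who already have subject-level functional-connectivity (FC)
matrices — symmetric region-by-region Pearson correlations with unit
diagonal — and want a graph-attention classifier that treats positive and
negative correlations as separate signed graphs and fuses several
sparsification levels ("views") of each connectome. The package also
ships a synthetic-cohort generator with planted, tunable group
differences, so the whole pipeline is testable without any imaging data.

## The model

For each subject the FC matrix `C` is split into nonnegative halves
`C⁺ᵢⱼ = max(Cᵢⱼ, 0)` and `C⁻ᵢⱼ = max(−Cᵢⱼ, 0)` (off-diagonal), and each
half is sparsified at V increasing edge-retention fractions ρ₁ < … < ρ_V,
giving 2·V graphs per subject. Per view and sign channel:

1. **GAT-1** — graph attention (Veličković-style): `h′ᵢ = W hᵢ`,
   `eᵢⱼ = LeakyReLU(aᵀ[h′ᵢ ‖ h′ⱼ])`, `αᵢⱼ = softmax_{j∈𝒩ᵢ}(eᵢⱼ)`,
   `h⁰ᵢ = Σⱼ αᵢⱼ h′ⱼ`, with first-order neighborhoods (plus self) from the
   view adjacency;
2. **residual addition** with a projected skip of the raw node features;
3. **GAT-2**, whose mean-pooled `+`/`−` outputs are concatenated
   (128-wide at defaults) into a per-view Linear(128,16)→Linear(16,2)
   auxiliary head;
4. a **transformer encoder** (pre-norm; softmax(QKᵀ/√d_k)V multi-head
   attention, ReLU feed-forward) over the node tokens of each sign.

The per-view encoder outputs are then folded by **cross-view transformer blocks** — LayerNorm both views, multi-head attention with
queries from the running state and keys/values from the next view, two
residual additions around an MLP — separately for the positive and
negative branches. The last two fold outputs of each branch are
mean-pooled and concatenated (384-wide at defaults) into the fusion head
Linear(384,32)→Linear(32,16)→Linear(16,2), whose logits give the
diagnosis. Training minimizes the fusion cross-entropy plus λ times the
per-view head cross-entropies (λ = 0.5 by default).

The network is implemented over a small in-repo reverse-mode autodiff
engine (float64 numpy), which keeps the stack dependency-light, fully
deterministic under a seed, and directly verifiable by finite
differences.

## Worked example

```python
from mvgat import (SimConfig, simulate_cohort, RunConfig, ModelConfig,
                   ViewConfig, OptimizerConfig, cross_validate)

samples, manifest = simulate_cohort(SimConfig(effect=0.4, seed=0))
cfg = RunConfig(model=ModelConfig(), views=ViewConfig(),
                optimizer=OptimizerConfig(epochs=25), cv_folds=5, seed=0)
reports, summary = cross_validate(samples, cfg)
print({k: round(v, 3) for k, v in summary.items()})
```

prints (exact values; the pipeline is deterministic given the seeds)

```
{'accuracy_mean': 0.99, 'accuracy_sd': 0.02,
 'sensitivity_mean': 0.98, 'sensitivity_sd': 0.04,
 'specificity_mean': 1.0, 'specificity_sd': 0.0,
 'auc_mean': 1.0, 'auc_sd': 0.0}
```

i.e. with a strongly planted inter-module hypo-connectivity effect
(class 1's designated cross-module correlation reduced by 0.4), stratified
5-fold cross-validation separates the two classes almost perfectly; at a
weak effect (0.1) accuracy drops to ~0.75, confirming the model tracks
the planted signal rather than noise. The same pipeline is available from
the shell:

```sh
mvgat simulate --out cohort/
mvgat cross-validate --manifest cohort/manifest.tsv --folds 5 --seed 0 --json cv.json
mvgat train --manifest cohort/manifest.tsv --out run/
mvgat evaluate --checkpoint run/checkpoint.npz --manifest cohort/manifest.tsv
mvgat predict --checkpoint run/checkpoint.npz --matrix cohort/sub-0000.csv
```

## Data formats

- **FC matrix**: delimited text (comma/tab autodetected), N×N, no header.
- **Manifest**: TSV with header `subject_id  path  label` (labels 0/1;
  paths relative to the manifest).
- **Checkpoint**: single `.npz` archive of parameter arrays keyed by
  module path plus the model config; load/evaluate round-trips bitwise.
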