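# Methods

## Problem and model

`catcpi` predicts whether a small molecule interacts with a protein target
(CPI) or with a second small molecule (DDI) from two modality-specific
representations fused by convolution:

1. **Compound branch.** The SMILES string is rendered to a 2D structural
   depiction (RGB raster, white background, values in [0, 1]) and passed
   through a CNN block of Conv → BatchNorm → LeakyReLU(α = 0.01) → MaxPool
   stages. The resulting map `W0 ∈ R^{C×H×W}` is flattened
   *channels-as-tokens*: row i of `W1 ∈ R^{N×D}` is the row-major flattening
   of channel i, so N = C and D = H·W. Fixed sinusoidal position embeddings
   `PE(pos, 2i) = sin(pos/10000^{2i/D})`, `PE(pos, 2i+1) = cos(pos/10000^{2i/D})`
   are added, and a pre-norm transformer encoder
   (`z ← z + DropPath(MSA(LN(z)))`; `z ← z + DropPath(MLP(LN(z)))`)
   produces the compound feature map `Xc ∈ R^{N×D}`. Attention is scaled
   dot-product, `softmax(QKᵀ/√Dh)V`, with per-head width Dh = D/k so compute
   is constant in the head count k.

2. **Protein branch.** The sequence (20 standard residues plus a single
   unknown class 'X') is segmented by a stride-1 sliding window into k-grams,
   raising the effective alphabet to up to 20^k sub-sequence types. A corpus
   built from the *training split only* numbers each observed k-mer
   (reserved ids: pad = 0, unknown = 1; novel or X-containing k-mers map to
   unknown). Sequences are encoded to exactly N token ids — padded when they
   produce ≤ N windows, otherwise subsampled at evenly spaced start
   positions round(j·(W−1)/(N−1)) (length-proportional subsampling; plain
   truncation is available behind `protein_subsample="truncate"`). A learned
   embedding table (pad row zero-initialized) maps ids to R^D, and a second
   transformer encoder with identical architecture but separate weights
   yields `Xp ∈ R^{N×D}`.

3. **Feature relearning (FR).** `Xc` and `Xp` are stacked as a 2-channel
   tensor `R^{2×N×D}` and re-learned rather than compressed:
   Conv2D (2→16, 3×3, BN, LeakyReLU, MaxPool 2×2) → reshape (post-pool
   channels become 1D channels, flattened spatial positions the length) →
   Conv1D (16→32, kernel 3, BN, LeakyReLU, MaxPool 2) → flatten → MLP
   (one hidden layer) → linear → sigmoid probability. The first
   convolution sums compound and protein contributions at aligned
   positions, which is what couples the two modalities.

In DDI mode both SMILES pass through the *same* compound branch (shared
weights); the two maps are stacked and fused identically.

Training minimizes binary cross-entropy
`−(1/N) Σ [yₙ log Pₙ + (1−yₙ) log(1−Pₙ)]` with Adam. Internally the loss is
evaluated from the logit via the softplus identity
`softplus(l) − y·l` — numerically identical, but the gradient does not
vanish when predictions saturate against the probability clip
(ε = 10⁻⁷), which matters early in training. Reported losses are the same
quantity.

## Defaults and why

| parameter | default | note |
|---|---|---|
| image size | 128 px | training default; 64/256 for the size sweep |
| CNN stages | 3→16→32→64→64 ch, 3×3, stride 1, pad 1 | final C = 64 fixes N |
| pooling plan | 2×2 pools on the first log2(S/16) stages | 128 → (64, 16, 16), so D = 256 |
| k (k-gram) | 3 | 20³ = 8000 sub-sequence types; configurable 1–4 |
| N, D | 64, 256 | protein map matches the compound map for stacking |
| encoder | depth 4, heads 8, mlp_ratio 4, DropPath 0.1 | LeakyReLU in the MLP, matching the rest of the architecture |
| FR | 2→16 (2D), 16→32 (1D), hidden 512 | all configurable |
| optimizer | Adam, lr 0.001, batch 128, 30 epochs | conventional β/ε, no weight decay, no early stop |
| threshold | 0.5 | for precision/recall/F1 |

Attention scale: the normalization divides by √Dh (the scaled-dot-product
form); BatchNorm uses momentum 0.1 with affine parameters and running
statistics in evaluation mode. The final classifier layer is
zero-initialized so every model starts at p = 0.5 exactly, which removes a
transient saturation spike in the first optimizer steps.

Protocol: `fit_protocol`/`run_protocol` performs n (default 5) independent
runs; each run derives its seed from the master seed, re-splits 8:1:1,
re-initializes, and trains; the run with the best validation ROC-AUC is
"selected" and the mean ± std of test metrics across runs is reported.
Vocabulary construction always uses the training split of the current run.

## Synthetic data: what it emulates and what it does not

Real CPI tables (compound SMILES, protein sequence, binary label) are
emulated by 56 drug-like scaffolds instantiated with 22 randomized
substituents (all 1232 combinations parse and render), and proteins drawn
uniformly over the 20-letter alphabet with an optional independent
'X'-corruption rate in [0, 0.1]. Labels come from a planted rule: a
designated substructure token in the SMILES (a carboxyl fragment) AND a
designated 4-mer motif in the protein; DDI labels require two tokens
co-occurring across the pair. Positives are constructed (token-bearing
compound resampled, motif spliced at a random position) and negatives
resampled until the rule does not fire (bounded attempts, then a
generation error naming the rule), so positive counts are exact —
round(n·positive_fraction) — and a non-learned oracle applying the rule
scores ROC-AUC 1.0. Any end-to-end learning failure is therefore a model
defect, not label noise.

What passing these tests does *not* show: real proteins are not i.i.d.
uniform sequences (no domain structure, no homology between train and
test), real label rules are not single-motif conjunctions, and real
datasets carry activity-derived label noise and class imbalance (e.g.
Kd-thresholded labels). Results on the synthetic sets validate the
machinery, not chemistry.

## Numerical engine

The network core (convolutions, batch/layer norm, attention, Adam, reverse-
mode gradients) is a compact numpy autograd engine (`catcpi.nn`). Ops are
vectorized over batches; convolutions use im2col + GEMM; normalizations are
fused single ops with the standard closed-form backward; pooling routes the
gradient to the first arg-max per window (deterministic under ties, which
occur on white backgrounds). Parameters are float32; graphs built from
float64 inputs stay float64, which is what the oracle-comparison tests use.
Every source of randomness (initialization, batching, DropPath, splits,
synthetic data) descends from explicit integer seeds, so a fixed master
seed reproduces byte-identical protocol results.

## Test- and example-scale configuration

`ModelConfig.reduced()` — 64×64 images, depth 2, heads 4, CNN pooled to an
8×8 grid (D = 64), DropPath 0, FR hidden 256, batch 32 — is the scale used
throughout the test suite, the worked example and the acceptance script;
it trains a 1000-record planted-rule set to test ROC-AUC ≈ 0.98 in minutes
on one CPU core. The learnability checks train this configuration for up
to 50 epochs (stopping once training ROC-AUC reaches the asserted level)
on 128 records, and for 8 epochs per seed on 1000 records, where the
validation AUC plateaus within the first few epochs. The acceptance script
uses 600 records × 6 epochs × 3 runs (CPI), 300 records (DDI), and a
300-record horizontal-flip robustness experiment. These sizes are the
package's own benchmark conditions; the full-size defaults above remain
available unchanged.

## Geometric robustness suite

Four protocols perturb every compound depiction: rotation (1/4 of
compounds each at 90°/180°/270°, remainder unchanged), horizontal and
vertical flips (1/2 flipped), and reduce-and-translate (depiction
downscaled by area-averaging to h×w, pasted on the white S×S canvas flush
into one of the four corners — 1/4 per corner, remainder to the last
corner — so the patch center is displaced by half the size difference,
⌊(S−h)/2⌋ and ⌊(S−w)/2⌋, per axis). Images are indexed (channel, row,
col), row 0 at top; rotations are counter-clockwise. Group sizes use
⌊n/4⌋ (or ⌊n/2⌋) with leftovers untransformed so the transformed fraction
never exceeds the nominal one. The harness retrains on transformed images
and reports the test-AUC delta; no numeric bound is asserted because the
deltas are data-dependent.

## Known limitations

- Scale of the depicted structure varies between molecules (no canonical-
  scale normalization), mirroring standard 2D depictions.
- No atom-level annotation channels or 3D conformers; the image is the
  only compound input.
- The CNN stage widths, FR sizes, encoder depth/heads and epoch budget are
  declared defaults, not values fitted to any external dataset.
- Training is single-threaded CPU numpy; wall-clock is dominated by
  memory traffic on feature maps, and large-scale runs (10⁵ records,
  256×256 images) are out of practical reach of this engine.
- Single-class evaluation sets yield flagged, undefined AUCs (`NaN` with
  `auc_defined = False`); threshold metrics are still reported.
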