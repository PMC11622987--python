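# Methods

This note documents the models, numerical choices and limitations of the
package in the package's own terms.  Empirical statements below are all
recomputed by the test suite or `scripts/acceptance.py`.

## Region condensation

A region with `np_i` voxels and `nr_t` time points (1 for structural MRI)
becomes a square array by flattening the `np_i x nr_t` value matrix
row-major (voxel-major, time-fastest), zero-padding, and reshaping to
`side x side x channels` (3 channels for fMRI, 1 for MRI).  The side is the
smallest multiple of 10 with `side^2 * channels >= np_i * nr_t`; this is
the unique simple rule consistent with both worked sizes (1,000 x 140 x 3
→ 220; 1,500 x 1 → 40).  The granularity (10) is configurable.  Padding is
exactly zero and recorded in `pad_count`, so condensation is invertible up
to padding (property-tested).  Voxels are scanned in z-major raster order
(C order of the label grid) for reproducibility.

**Dataset-uniform sides.**  The pipeline pads every region of a cohort to
the maximum side the rule assigns (`make_region_array(..., min_side=...)`).
Rationale: two regions' arrays are only cell-aligned — voxel v, time t in
the same raster cell — when they share one layout.  Alignment is what lets
a *shared* projection preserve inter-regional correlation structure.  The
per-region rule and its printed examples are unchanged; uniformity only
adds padding.

## Backbones as frozen random projections

The Alex-/VGG-/ResNet-style encoders are scaled-down renditions (default
stage widths 8/16/32, config-driven) with He-normal weights drawn once from
a seeded generator and then frozen: at desk scale, training the encoders
end-to-end (the original regime, GPU-scale) is out of scope, and seeded
random-feature projections keep every downstream result deterministic and
testable.

Two deliberate deviations from the classic layouts follow from the frozen
regime, both verified numerically during design:

* **Flatten + dense head, not global average pooling.**  The 256-unit dense
  block reads the flattened final feature map.  Global averaging is a
  spatial low-pass; in the condensed raster layout *time is the fastest
  axis*, so spatial averaging averages over time samples and removes the
  inter-regional coupling information the association networks need
  (feature-cosine correlation with the Pearson proxy drops from ~0.8 under
  a shared linear projection to ~0.07 after conv + pooling stacks).
* **Stride-2 decimation as the default downsampler.**  Max/avg pooling are
  low-passes with the same time-averaging effect; decimation subsamples
  time instead of averaging it and retains the coupling signal (~0.34
  cosine-proxy correlation through the full stack).  Classic max or average
  pooling remain available (`BackboneSpec(pool="max"|"avg")`).

The downsampling count adapts to the input side: the largest number of
stride-2 halvings that leaves the spatial side >= 4 (40 → 3, 220 → 5).
The floor of 4 is our choice; only the adaptivity itself is prescribed.

## Normalized group activations

Default activation set: ReLU, ELU, ELiSH.  The ELiSH implementation is the
standard one (`x·σ(x)` for `x >= 0`, `(e^x − 1)·σ(x)` for `x < 0`); the
variant sometimes printed as `(e^x − 1)/(1 + e^x)` (i.e. `tanh(x/2)`) is
selectable as `elish_printed`.

Statistics: per-unit, per-activation min/max frozen from a class-balanced
mini-batch of ~20% of the training data, never updated afterwards (this is
not batch norm).  ε = 1e-6 (our choice) keeps the estimation-batch values
in [0, 1); values outside the batch range are clipped to [0, 1] at
inference — boundedness is required, the clipping mechanism is ours.

Initialization: the published initial state (η = 1/m, κ = 0, γ = 1) makes
the layer output identically 1 until κ/γ move, so learning starts from a
constant feature; it is available as `init="paper"` and is tested.  The
default is η = 1/m, κ = 1, γ = 0, which starts the layer as the mean of the
normalized activations (identity-like) and trains faster at desk scale.
The η ∈ [0,1] constraint is enforced by projection (clipping) after every
optimizer step; gradients of the layer pass a 1e-5 relative numerical
check.

## Regional association networks

Architecture: concatenate `[|x1 − x2|, x1 ⊙ x2]` (elementwise-symmetric, so
score symmetry holds architecturally, untrained included) → dense(128) +
NGA → dense(32) + NGA → dense(1) + sigmoid.  Supervision is a similarity
proxy in [0, 1]: for fMRI `(Pearson r of the regions' mean time series +
1)/2`, for MRI `(cosine of the condensed vectors + 1)/2` — the
connectivity-network lineage this design descends from trains on exactly
this kind of regional-similarity target.  Training: Adam (β1 0.9, β2 0.99),
lr 1e-4, batch 5, 15 epochs, mean-squared error; the nets are then frozen.
One net per pair is the printed configuration; a shared net
(`shared_net`) is the desk-scale default in the pipeline.

The pair-score image is the full symmetric `k x k` matrix per backbone
channel with diagonal fixed at 1 (self-association; our convention).  The
alternative of packing the `k(k−1)/2` scores into a smaller square is
available (`assembly="packed"`) but the matrix preserves region-pair
geometry for attention interpretation.

## Classifier and rollout

A small pre-norm vision transformer (defaults in the pipeline: patch 4,
embed 32, 4 heads, depth 1, MLP 64; all configurable) on zero-padded
patches with a class token and learned positional embeddings.  Phase-2
training is cross-entropy with Adam.  The published schedule (lr 1e-5, 50
epochs) is tuned to a GPU-scale model; it underfits the desk-scale ViT, so
the pipeline default is lr 1e-3 for 50 epochs.  Both phases' settings are
plain keyword arguments.

Gradient rollout: per block, the post-softmax attention is fused with its
gradient with respect to the target-class logit (elementwise product,
negative parts clamped to zero, head-averaged), the identity is added and
rows renormalized (residual adjustment), the per-block maps are multiplied,
and the class-token row is reshaped to the patch grid and bilinearly
upsampled to the pair grid, clipped at zero and max-normalized.  For a
1-block model this reduces to the fused attention directly (oracle-tested).
The recipe is the gradient-weighted variant; it is isolated in
`gradient_rollout` and swappable.

## Heterogeneous feature stages

* **GLCM**: uniform quantization to 16 gray levels (configurable; the level
  count is our choice), 13 antipodally-unique directions of the
  26-neighbourhood, distances 1–3, symmetric and normalized counts, and the
  classical 11-descriptor set (angular second moment, contrast,
  correlation, variance, inverse difference moment, sum average, sum
  variance, sum entropy, entropy, difference variance, difference entropy)
  — 429 features per block.  The feature *count* is prescribed; the named
  list is the classical set, documented in the schema.
* **RROI**: non-overlapping `B_l x B_l` tiling (defaults 15 and 21) from
  the origin, row-major, partial tiles dropped (not padded — keeps block
  statistics unbiased); per block: mean and central moments 2–4 plus
  contrast, entropy, inverse difference moment and homogeneity from an
  in-block 2-D co-occurrence matrix.
* **3-D DWT**: separable tensor-product transform with periodized
  orthonormal filters (default Daubechies-2; Haar available).  Per level:
  one approximation + seven orientation detail groups, each downsampled by
  2 per axis.  Perfect reconstruction and energy conservation hold to 1e-8
  relative over 20 seeds (tested).  Filters are hard-coded standard
  coefficients; no wavelet library is required.
* **Scattering**: Gaussian low pass + Morlet band passes built in the
  Fourier domain (2-D: L equiangular orientations; 3-D: a fixed
  orientation set on the hemisphere), modulus between layers, order <= 2,
  frequency-decreasing paths only; coefficients are per-path global
  averages.  Defaults J = 3, L = 4, order 2.
* **Plugins**: `register_transform(name, fn)` makes any deterministic
  array → array/vector stage selectable in the pipeline config
  (`feature_stage`), which is how shearlets/curvelets slot in from external
  libraries.

Stages operate volume-wise before region extraction where shapes allow
(wavelets use a level-1 approximation with a downsampled atlas);
vector-valued stages (GLCM/RROI/scattering) apply per region to the
region's bounding box, the descriptor becoming the region's value column.
Whether such features should replace or augment raw values is not
prescribed; the pipeline replaces (config-switchable by stage choice).

## Evaluation protocol

Binary metrics: accuracy, sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)`.  Ternary: per-class precision over the predicted-as-class
column, recall over the true-class row (the only reading that makes the
cross-class terms the standard precision/recall pair), F1 harmonic mean,
accuracy = trace/total.  Repeated random splits: per repeat, sample
`floor(f · n_minority)` of the minority class (f = 0.70 fMRI / 0.90 MRI)
and an equal count of every other class for training, carve a validation
fraction (0.10 fMRI), everything unselected is the test set; 25 repeats by
default, means (and sd, our addition) reported.  AUC uses the trapezoidal
ROC rule (scikit-learn's `roc_auc_score`).  A k-fold option exists but the
repeated-split protocol is the implemented default.

## Synthetic data: what it emulates, and what a green test establishes

The generator produces a Voronoi parcellation of a cubic grid (default
24^3, 12 regions), 3 classes, and per class: designated coupled region
pairs whose latent series share a common component (`l = sqrt(ρ)·z_common +
sqrt(1−ρ)·z_own`, so the latent correlation is exactly ρ; default 0.8) for
fMRI, and designated regional mean-intensity shifts for MRI.  Voxel noise
is Gaussian (sd 0.5).  The mean regional series over `nv` voxels attenuates
noise by `1/sqrt(nv)`, giving the analytic empirical correlation `ρ / (1 +
sd²/nv)` that the tests check by simulation.  nr_t defaults to 140 data
points per subject.

Not modelled: hemodynamics, scanner artefacts, spatial autocorrelation of
noise, longitudinal drift, registration error.  A green end-to-end test
therefore establishes that the pipeline machinery recovers planted
class-conditional coupling/atrophy structure — not that it would reach any
particular accuracy on real cohort data.

## Known limitations

* **Frozen backbones.**  Without end-to-end encoder training, pair evidence
  reaches the association nets only through aligned random projections;
  the decimation/flatten choices above are required for that channel to
  exist at all, and it is noisier than a trained encoder's.
* **Strict rollout localization fails at desk scale.**  The saliency-
  contrast property (injected pairs scored above the average pair) holds in
  every seeded run, but requiring the injected pairs to sit in the top
  decile of saliency does not: saliency is patch-granular (3x3 patches over
  a 12x12 pair grid), bilinear upsampling spreads mass, and with a 3-class
  softmax the *absence* of coupling in other classes' blocks is equally
  valid evidence that rollout legitimately credits.  The corresponding
  acceptance test is left failing by design rather than weakened.
* The per-pair (6,670-net) configuration is implemented but impractical on
  one CPU; the shared-net configuration is the tested path.
* The transformer's printed learning rate (1e-5) is preserved as the
  default constant in the CLI config but every desk-scale example overrides
  it; see above.
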