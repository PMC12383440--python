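# Methods

## Model

The network is a prompt-conditioned binary segmenter trained separately per
task (WT, TC, ET). Each of the N modality images (grayscale replicated to
3 channels, values in [0,1]) passes through one shared-weight encoder. The
built-in `light_trainable` encoder is two stride-2 3×3 convolutions with ReLU
(C₁ channels, spatial stride 4); `foundation_frozen` is a contract for an
external pretrained vision-transformer encoder loaded from a checkpoint and
never updated — it is not shipped and no test depends on it.

The Feature Fusion Block concatenates the N feature maps into F_c with
C₂ = N·C₁ channels and computes squeeze-and-excitation channel attention:

- squeeze: z_k = (1/HW) Σ_{h,w} F_c(k,h,w)
- excite: s = σ(W₂ δ(W₁ z)) with δ = ReLU, σ = sigmoid, bottleneck width C₂/r
- modulate: F_fm(k) = s_k · F_c(k)
- residual: F_f = proj(F_fm + F_c), proj a learned 1×1 convolution to the
  decoder width.

The residual form is a genuine design choice: "add then project" preserves the
identity path that the term residual implies while adapting the channel count
to the decoder. The SE ratio defaults to r = 16 (the standard SE choice) with
C₂/r ≥ 1 enforced; the CPU test profile uses r = 8 because its C₂ is only 32.

The prompt is the mask's tight bounding box (0-based, inclusive corners,
x = column), each side pushed outward by an independent uniform integer in
[0, 20] pixels during dataset construction — outward only, so the prompt never
excludes tumor — and clamped to the image. The light prompt encoder embeds the
four corner coordinates, normalized by the image size, with one linear layer;
the decoder adds the embedding to every spatial position of the fused map,
then applies conv–ReLU, 2× nearest upsample, conv–ReLU, 2× upsample, conv,
yielding one logit per pixel at input resolution. A pixel is foreground when
its logit ≥ 0 (sigmoid 0.5; the tie counts as foreground, arbitrary but fixed).

All layers are NumPy with explicit backward passes (im2col convolutions);
gradients are verified against central finite differences in the test suite.
Optimization is AdamW (decoupled weight decay, biases excluded) with the
configured trainable parts only — the frozen-parts contract is asserted
bitwise after every training run.

## Missing-modality scheme

A substitute image has every element i.i.d. Uniform(0,1) — the same scale as
the normalized inputs, which is why substitution happens after preprocessing.
During MT training each designated modality draws p ~ U(0,1) per sample per
iteration and keeps the real image iff p ≤ λ (default λ = 0.5); the redraw
granularity maximizes augmentation diversity. At prediction, FP passes inputs
through untouched and MP always substitutes. Three independent seeded RNG
streams (init, shuffling, substitution) guarantee that FT and MT(λ=1) produce
bit-identical loss trajectories: λ=1 consumes substitution draws but never
acts. Experiments designate one missing modality at a time (arbitrary subsets
are supported); the mode grid trains one MT model per scenario.

## Objectives and metrics

Training loss: soft Dice loss 1 − 2Σyŷ/(Σy² + Σŷ² + ε) with ε = 1e-6 (guards
the 0/0 case that slice selection already excludes) plus mean binary
cross-entropy, computed in the numerically stable logit form. Evaluation Dice
is 2|G∩S|/(|G|+|S|), with both-empty defined as 1. HD95 extracts the
8-connectivity boundary of each mask, computes both directed
nearest-neighbour distance lists, takes the 95th percentile (linear
interpolation) of each and the maximum of the two — the standard
outlier-robust reading; the plain maximum (classical Hausdorff) is exposed as
`hausdorff`. Distances are Euclidean in pixels at model resolution; whether to
report millimetres at native resolution is a dataset question the package
leaves to its caller. An empty prediction against a nonempty target scores the
image diagonal and the row is flagged so users can exclude it. Aggregation is
per-slice (the pipeline is 2-D); size-stratified Dice uses [0,500), [500,1000),
… pixel bins.

## Preprocessing

"Removing" voxels outside the 0.5–99.5 percentile band is implemented as
clamping to the band edges — deletion would break the voxel grid; the retained
band is scaled affinely to [0, 255]. Percentiles use linear interpolation over
all voxels including background zeros (documented because skull-stripped
backgrounds shift percentiles). A constant volume maps to all zeros with a
warning. Clamping ties ~0.5% of the voxels at each band edge, so a second pass
is idempotent only to one quantile spacing (~range/n); the tests assert that
resolution. Task masks follow the concentric convention WT = {1,2,3},
TC = {1,3}, ET = {3}. Tumor-containing slices are selected along Z per task.
Images are resized bilinearly to the model size (anisotropically for
non-square inputs — one fixed model resolution, no padding), masks with
nearest neighbour; metrics are computed at model resolution.

## Phantoms

A subject is three nested regions — deformed spheres with radii
(r_whole, r_core, r_enh), strictly decreasing — whose boundaries are perturbed
radially by a random combination of degree-1/2 real spherical harmonics,
normalized to a peak amplitude `deform_amplitude` (exact spheres would make
boundary metrics degenerate). Amplitude is capped at 25% of the smallest
radius gap so independent per-region perturbations cannot break nesting; the
generator also enforces nesting by intersection. Labels use the concentric
convention: edema analog = whole − core, necrosis analog = core − enhancing,
enhancing analog = innermost region. Each modality's image is
`background + Σ_region contrast·indicator` plus additive Gaussian noise
clipped at 0 (no Rician model; the method under test is noise-model agnostic).
The default contrast matrix gives the FLAIR-like modality the whole-lesion
signal and makes the T1gd-like modality the *only* carrier of core/enhancing
contrast — the modality-importance structure that makes the robustness
experiments meaningful. Defaults: 32×48×48 voxels, radii (14, 8, 4),
background 0.15, noise σ = 0.04, deformation 1 voxel, ±10% per-subject
radius/contrast jitter (clamped to keep the whole region inside the volume).

What the phantoms do not emulate: MRI physics, bias fields, multi-focal or
non-concentric tumors, registration error, inter-rater label noise. Passing
tests therefore demonstrate that the architecture, training scheme and
bookkeeping behave as specified on data with the assumed information
structure — not clinical-grade accuracy on patient data.

## Experiment harness and problem sizes

Training is plain mini-batch AdamW, constant learning rate, no schedule, no
early stopping, fixed epochs. Cross-validation partitions at the subject
level (no subject's slices span folds). The mode grid trains FT and MT on a
shared subject split and initialization — only the policy differs — and
evaluates each under FP and MP; MP evaluation is stochastic and is averaged
over ≥3 fresh noise draws with the spread reported. The λ sweep trains one MT
model per λ with shared seeds, so its λ=1 row coincides bit-for-bit with FT.
Fused features (spatially pooled F_f) are embedded with seeded UMAP.

Two profiles exist. The reference configuration keeps the full-scale settings
(1024×1024 inputs, batch 8, lr 1e-4, weight decay 0.01, 50 epochs, 5 folds).
The desk profile (`desk_config`) — used by the tests and the acceptance
script — runs the light encoder at 64×64 with C₁ = 8, r = 8, decoder width 16,
lr 3e-3, 4–8 epochs, cohorts of ~10 subjects, and thins WT slice datasets to
every other z; these sizes were chosen as the smallest at which training
reliably converges to held-out Dice well above 0.85 so that every experiment,
including the 5-seed robustness comparison, completes in minutes on one CPU
core. The higher learning rate compensates for the few epochs; it is a
profile parameter, not a change to the reference configuration.

## Known limitations

- The foundation-encoder path is a contract only; the shipped encoder is the
  light convolutional one.
- Uniform-noise substitution is the only imputation mechanism; generative or
  modality-aware imputation is out of scope.
- Significance testing between modes is not implemented.
- Multi-class (single-model) segmentation is not supported: one binary model
  per task.
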