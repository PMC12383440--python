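# modfuse

Multi-modal MRI brain-tumor segmentation with channel-attention feature fusion
and missing-modality robust training.

Gliomas are imaged with several co-registered MRI sequences (T1, contrast-enhanced
T1gd, T2, FLAIR, and DTI-derived maps), and the three nested target regions —
whole tumor (WT = necrosis ∪ edema ∪ enhancing), tumor core (TC = necrosis ∪
enhancing) and enhancing tumor (ET) — are each best seen in different sequences:
FLAIR dominates WT, T1gd dominates TC/ET. In clinical practice individual
modalities are frequently missing. `modfuse` implements and tests a
prompt-conditioned segmentation pipeline built for exactly this situation:

- **Per-modality encoding.** One shared-weight encoder maps each modality image
  X₁…X_N to a feature map F₁…F_N. A small trainable convolutional encoder
  (pure NumPy, explicit backprop) is built in; a frozen pretrained foundation
  encoder is a pluggable alternative.
- **Feature Fusion Block (FFB).** The maps are concatenated into F_c
  (C₂ = N·C₁ channels) and reweighted by squeeze-and-excitation channel
  attention: z = GAP(F_c), s = σ(W₂ δ(W₁ z)), F_fm = s · F_c, followed by a
  residual combination F_f = proj(F_fm + F_c).
- **Box-prompted decoding.** A learned embedding of the ground-truth-derived
  (jittered) bounding box conditions a convolutional decoder that upsamples the
  fused map to a per-pixel logit.
- **Missing-modality training (MT).** During training a designated modality is
  kept with probability λ and otherwise replaced by a fresh Uniform(0,1) noise
  image (per sample, per iteration); at prediction time a missing modality is
  always replaced by noise (MP) or all modalities are supplied (FP). λ = 1
  reduces MT to full-modality training (FT).
- **Objectives and metrics.** Total loss = squared-denominator soft Dice loss +
  binary cross-entropy. Evaluation uses the Dice coefficient and the
  95th-percentile symmetric boundary Hausdorff distance (HD95), plus
  size-stratified Dice aggregation.
- **Synthetic phantoms.** A generator produces cohorts of multi-modal volumes
  with nested deformed-sphere lesions and a modality-specific contrast matrix
  that mirrors the FLAIR-for-WT / T1gd-for-TC structure, so the entire pipeline
  — NIfTI I/O, preprocessing, training, the FT/MT × FP/MP mode grid, the λ
  sweep, fused-feature UMAP embedding — runs end-to-end with no data download.

## Worked example

```python
import modfuse as mf

cohort = mf.generate_cohort(mf.PhantomSpec(seed=7), 10)
cfg = mf.desk_config(task_seed=0, epochs=5)          # 64x64 CPU profile

results = mf.mode_grid_eval(cohort, "TC", cfg, "T1gd")
print(mf.grid_table(results).to_string(index=False))
```

prints (Dice over held-out subjects of the core-region task when the T1gd-like
modality — the only one carrying core contrast — may be missing):

```
mode missing  n_slices  mean_dice  sd_dice  mean_hd95
FTFP    T1gd        49   0.939428 0.058113   1.130211
FTMP    T1gd       147   0.440238 0.195373  14.490049
MTFP    T1gd        49   0.892207 0.092175   1.637312
MTMP    T1gd       147   0.727472 0.191515   4.939975
```

Reading the grid: with full inputs the model segments the core well (FTFP
0.94). If the key modality disappears at prediction time, a conventionally
trained model collapses (FTMP 0.44), while the same architecture trained with
stochastic modality dropout recovers most of the loss (MTMP 0.73) at a small
full-input cost (MTFP 0.89) — the robustness effect the missing-modality
training scheme exists to produce.

A thin CLI wraps the same stages:

```bash
modfuse --out runs/demo phantom --n-subjects 10
modfuse --out runs/demo mode-grid --task TC --missing T1gd
```

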