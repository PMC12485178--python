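# Methods

## Problem and approach

Diabetic-retinopathy (DR) grading assigns a fundus photograph one of five
ordinal severity stages (0 = no DR … 4 = proliferative). Labeled clinical
data are scarce and ImageNet-style transfer is hampered by the domain gap, so
this package pretrains its encoder on unlabeled fundus images with a
self-supervised objective and evaluates the learned representation by linear
probing and fine-tuning, scored with the quadratic weighted kappa that is
standard for ordinal DR grading.

The encoder is deliberately multi-scale. A vision transformer (the global
feature extractor, GFE) supplies image-wide context through self-attention; a
ResNet with a feature-pyramid network (the fine-grained feature extractor,
FFE) supplies local detail at strides 4, 8 and 32 (levels P2, P3, P5). The P3
and P5 maps are bilinearly resized to the P2 grid and concatenated; the ViT
patch tokens are reshaped to their grid, projected 1×1 to the same width and
resized; the two stacks are combined element-wise (addition by default;
concatenation and multiplication are configurable ablations). A Deep Learner
(DLe) refines the fused map through transposed-convolution stages (kernel 3,
stride 2, padding 1, output padding 1 — each stage exactly doubles the
spatial side) with ReLU nonlinearities, gated by a CBAM attention block at
the end; 1-D and same-resolution 2-D convolution stacks exist as ablation
paths, as do CBAM-first and no-attention variants.

## Pretraining objectives

Training follows the negative-pair-free momentum-encoder family. A teacher
network of identical structure tracks the student by exponential moving
average, `t ← m·t + (1−m)·s` with `m = 0.996`; no gradient ever flows through
it. Two augmented views of each image (or the left/right views of one
dual-view eye, chosen with probability 0.5 when available) feed both
networks, and two losses are combined:

* **Representation matching** (self-distillation): cross-entropy between the
  teacher's centered, sharpened distribution
  `softmax((t − c)/τ_t)` and the student's `softmax(s/τ_s)`, symmetrized over
  the views. Defaults `τ_s = 0.1`, `τ_t = 0.04`; the center `c` is an EMA
  (momentum 0.9) of teacher projections. Centering plus sharpening is the
  canonical collapse guard for this family. The projection head is a 3-layer
  MLP on the ViT global token (hidden 2048, output 256 at full scale).
* **Segmentation**: binary cross-entropy plus soft Dice (equal weights,
  smoothing ε = 1) between the student's segmentation logits — a 1×1
  convolution on the DLe output, resized to image resolution — and a binary
  saliency mask. This is how saliency guides the pretraining: the masks are
  computed on the green channel, where lesions and vessels have the highest
  contrast, so the objective pushes features toward clinically salient
  regions.

`total = match + λ_seg · seg` with `λ_seg = 1` holds as an exact identity and
is asserted per step. The optimizer is AdamW (base LR 5e-4, weight decay
0.04 on matrix/conv weights only) with a cosine schedule.

## Preprocessing and augmentation

Images are reduced to the green plane, which is replicated to three channels
so standard three-channel backbones apply unchanged, scaled to [0, 1] and
standardized (mean 0.5, std 0.5). Black borders are cropped by the tight
bounding box of pixels whose maximum channel exceeds 10/255 — a threshold
robust to JPEG noise on nominally black frames.

Two saliency detectors are implemented. *Spectral residual*: the 2-D FFT
log-amplitude minus its 3×3 mean-filtered version is the residual; the
inverse transform of residual + phase, squared and Gaussian-smoothed
(σ = 2.5), is the map. *Fine-grained* (the default): the absolute difference
between each pixel and its box-filtered surround, summed over radii 3, 7 and
15. Both min-max normalize to [0, 1]; a constant image maps to all zeros.
Masks come from Otsu's threshold over the 256-bin histogram — parameter-free
and reproducible; the binarization rule is otherwise a free choice.

Augmentation follows the SimCLR recipe: random resized crop (scale 0.3–1.0 —
the lower bound is raised from 0.08 because the retina occupies the frame
center and extreme crops would sample pure background), horizontal flip
(p = 0.5), color jitter (0.4/0.4/0.4/0.1), Gaussian blur with a random odd
kernel (p = 0.5), then standardization. Geometric parameters are replayed
exactly on the mask; photometric operations skip it.

## Numerical foundation

All neural components run on a small reverse-mode automatic-differentiation
engine over float32 NumPy arrays (`msssl.nn`): tape-based, with im2col/col2im
convolutions, transposed convolutions, max pooling, nearest and bilinear
resampling (align-corners-false), batched matmul attention, and layer/group
normalization. Every structured operation is verified against central finite
differences in the test suite. GroupNorm replaces batch normalization in the
ResNet so outputs are independent of batch composition — a prerequisite for
the bit-exact determinism and resume guarantees. All randomness flows through
named substreams fanned out from one root seed; data order and augmentation
draw from per-(seed, epoch, batch) streams, so a run resumed from an epoch
checkpoint reproduces the uninterrupted run exactly. Checkpoints bind to a
digest of the structure-defining config blocks (encoder, DLe, preprocess);
loading into a structurally different model is refused rather than coerced.

## Synthetic data

The generator emulates only the gross structure of fundus photographs: a
green-dominant retina disc on a black frame (soft edge ≤ 2 px, exact zeros
outside), one elliptical optic-disc highlight, a dark random-walk vessel
tree, and lesions placed uniformly in the disc. Lesion counts are Poisson
with per-grade rates that must increase strictly with grade — default
(0, 2, 5, 10, 20); the evaluation benchmark uses (0, 4, 10, 18, 30) so a
lesion-count oracle separates grades with a detectable effect size. Each
lesion is a dark dot or bright blob with probability ½, loosely mimicking
hemorrhages versus exudates. Dual-view mode renders left/right views of one
eye sharing the lesion layout up to mirroring, with independent vessel noise.

What passing tests on this generator shows: that the pipeline end-to-end can
recover an ordinal, lesion-density-driven signal from unlabeled images well
above chance, and that every architectural and statistical contract holds.
What it does not show: performance on real fundus photographs — the
generator has no camera physics, no illumination variation, no lesion
morphology, and its grade signal is one-dimensional by construction.

## Desk-scale study configuration

The bundled benchmark and the acceptance script run a reduced configuration
chosen to exercise every module on one CPU: 64×64 images, ViT with patch 16,
embedding 64, depth 2, 4 heads; ResNet18 FPN with pyramid width 64 and stem
width 16; projection head 256→64; batch 8; 5 epochs over 300 images (60 per
grade). Linear evaluation extracts frozen features, standardizes them on
train statistics, fits a multinomial logistic head over a small
regularization grid and selects by validation kappa on a stratified 70/15/15
split. The label-shuffled null permutes every label the training pipeline
sees (train and validation) and is reported as the mean kappa over 16
decorrelated draws (a fresh split and a fresh shuffle each): a single draw at
test n = 45 has sd ≈ 0.2, because the head fitted to noise still aligns with
the dominant feature direction in a randomly ordered way.

## Design choices on open points

* **Downstream representation** (default `eval.representation: full`): the
  ViT global token concatenated with the spatially averaged DLe features.
  The segmentation objective concentrates lesion-sensitive features in the
  FFE/DLe path, and on the synthetic benchmark the full-path probe is
  substantially stronger (median kappa ≈ 0.78 vs ≈ 0.45 for the GFE-only
  token); the GFE-only probe remains available via `representation: gfe`.
* **Teacher scope**: the teacher mirrors the student's full structure (all
  parameters are EMA-tracked and checkpointed) but only its projection output
  is consumed, so its FFE/DLe forward pass is skipped at run time.
* **Both objectives on both views**, averaged — the symmetric choice.
* **Channel widths**: FPN width 256 at full scale (the usual FPN convention),
  GFE grid projected to 3·C_fpn before fusion; DLe halves channels per stage
  (floor, minimum 32).
* **DLe depth**: 2 stages, so P2-resolution input (stride 4) reaches image
  resolution with a single final resize of the segmentation logits.
* **Conv1D ablation** runs over the flattened spatial axis per channel; it is
  an ablation-only path with no claim of spatial meaning.
* **Bilinear resizing** for P3/P5 and the GFE grid (nearest only for the
  2× FPN top-down step, as in standard FPNs) to avoid blocky artifacts at
  8–32× upsampling.

## Known limitations

* The engine is single-threaded NumPy; full-scale (224 px, ViT-S) pretraining
  is possible but slow — the package is built for method correctness and
  desk-scale experiments, not throughput.
* The synthetic benchmark's grade signal is lesion count only; calibration,
  robustness to imaging artifacts, and real-data transfer are out of scope.
* Mixed precision, multi-process data loading and GPU execution are not
  implemented.
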