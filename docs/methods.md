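# Methods

## Model

An E-structure segmentation network consists of a staged encoder, a set of
per-stage upsampling units, an element-wise aggregation, one refinement
block and a pointwise classification head. The encoder contract is explicit
(`EncoderStageSpec`): in 2D, five stages at strides 2/4/8/16/32; in 3D, a
patch embedding at stride (4,4,2) followed by four stages whose in-plane
strides are 4/8/16/32 while the slice axis stays at stride 2, preserving
inter-slice resolution for thin volumes. Any encoder meeting the contract
can be converted into an E-model (`e_ify`); construction dry-runs the
encoder and validates every stage's stride and channel metadata.

Stage subsets are configurable. Defaults: 2D aggregates all five stages;
3D aggregates stages 2–5, excluding the patch embedding, whose coarse
features otherwise dilute the aggregation. The reference encoders shipped
here are small strided-convolution pyramids; the published full-scale
instantiations use pretrained image/video transformer-style backbones,
which this package deliberately does not bundle — the architecture is
encoder-agnostic and the package's claims are about the E-head, the blocks
and the metrics, all of which are exercised with the reference encoders.
The full-scale parameter totals printed for those backbone-based models
(30.88M / 31.74M) are therefore not reproducible here, and the
corresponding checks are expected to fail in this build.

### Blocks

* **GConv(k)** — pointwise conv → depthwise conv(k) → batch norm → ReLU.
  All convolutions are bias-free; this is what makes the closed-form
  budgets exact (`C_in·C_out + (k²+2)·C_out` in 2D, `k³` in 3D; the `+2`
  is the batch-norm affine pair).
* **DConv(3,r)** — GConv with kernel fixed at 3 and dilation `r`; padding
  `r` preserves shape, the receptive field is `2r+1` per axis, and the
  parameter count is independent of `r`.
* **MLKConv(C)** — stage 1: four GConv branches k∈{3,5,7,11}, each C→C/4,
  concatenated (ascending-k order) and mixed by a kernel-1 GConv added
  residually; stage 2: four DConv branches r∈{3,5,7,11} and a second
  kernel-1 mixer, added residually. Total parameters `4C² + 70C` (2D).
  The *final* mixer omits its ReLU so the residual correction can be
  signed; the stage-1 mixer keeps it. (The alternative reading — dropping
  the ReLU in both mixers — was considered and rejected: only the output
  layer needs an unclipped range.) With both mixers zero-initialized the
  block is exactly the identity, because the branch outputs only enter
  through the mixers; this is asserted bit-exactly in the tests.
* **UpConv** — kernel-3 conv to the aggregation width, then ReLU, then BN,
  in that order, then nearest-neighbor resize. The unconventional
  ReLU-before-BN order is the composition as specified for this
  architecture; a flag restores conv→BN→ReLU for ablation. UpConv refuses
  to downsample.
* **Refinement alternatives** for ablation: DoubleConv (two conv-BN-ReLU
  blocks), SE+BasicConv (squeeze-excitation gate then conv-BN-ReLU, with a
  gate-bypass switch used by the tests), or none (identity).

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `aggregation_width` | 64 (2D), 16 (3D desk) | channels after UpConv = MLKConv's C; must be divisible by 4 |
| `stage_subset` | 1–5 (2D), 2–5 (3D) | encoder stages entering the aggregation |
| `loss_weights` | (0.6, 0.4) 2D; (1, 1) 3D | Dice / cross-entropy mix |
| `refinement` | `mlkconv` | post-aggregation block |
| batch-norm momentum / eps | 0.1 / 1e-5 | conventional defaults |
| soft-Dice ε | 1e-5 | numerator and denominator smoothing |

Weight initialization is fan-out-scaled Gaussian for convolutions and
unit/zero for norm layers, driven by a single integer seed; inference-mode
outputs are bit-reproducible for a fixed seed.

## Compute core

No deep-learning framework is used. Layers are NumPy modules with explicit
analytic backward passes. Convolution has two execution paths that agree to
float rounding: a kernel-tap loop (any stride/groups/dilation) and an FFT
path (scipy `fftconvolve`) for stride-1 depthwise convolutions with more
than 32 taps, where the tap loop would dominate run time — the 11×11(×11)
MLKConv branches are the motivating case. Both paths, batch norm, the
nearest-resize adjoint and the loss gradients are verified against central
differences in float64. Training uses float32.

## Losses

Soft Dice uses one-hot targets, ε-smoothing, and by default averages over
the classes present in the target (an absent class otherwise contributes a
spurious near-zero Dice term); a flag includes all channels. Cross-entropy
is the mean per-pixel categorical loss on logits. The compound loss chains
the Dice gradient through the softmax Jacobian analytically.

## Metrics

DSC and IoU come from overlap counts and satisfy `DSC = 2J/(1+J)` exactly.
Surfaces are face-adjacency boundaries (4-neighborhood in 2D, 6 in 3D;
out-of-grid counts as background), with coordinates scaled by voxel spacing
so distances are physical. ASD is the pooled symmetric form with a single
`|S_X|+|S_Y|` denominator. HD95 takes the linear-interpolation 95th
percentile of each directed nearest-neighbor distance multiset separately
and returns the larger — the convention of the common evaluation tool
chain; under it HD95 ≤ the classic Hausdorff distance, with equality not
guaranteed for small sets. Distances use a k-d tree; the tests compare
against O(n²) all-pairs oracles at 1e-9.

Empty-set conventions are explicit and flagged in the report: class absent
from both masks → DSC 1, distances 0, flag `absent` (excluded from means);
absent from exactly one → DSC 0, distances set to the grid diagonal in
physical units, flag `pred_empty`/`gt_empty` (included in means). Mean DSC
excludes the background by default, switchable because some per-sample
analyses include it.

## Synthetic phantoms

The generator emulates the qualities that make medical targets hard —
blurred boundaries, irregular shapes, large size spans — with
perturbed-radius star blobs: an anisotropically scaled ellipse/ellipsoid
whose radius is modulated by low-order angular harmonics. Classes are
placed disjointly (with retry and a guaranteed-presence fallback) or
nested (later classes occlude). The image is the per-class contrast map,
Gaussian-blurred, noised, clipped to [0,1] and quantized to the 16-bit
grid so file round-trips are bit-exact. Everything is a pure function of
(spec, seed).

What the phantoms do *not* model: modality physics (CT calibration, MRI
bias fields, speckle), anatomical priors, inter-slice motion. Passing the
desk-scale pipeline therefore demonstrates that the architecture, losses,
optimizer and metrics are implemented correctly and can fit data — not
that the model segments clinical images at the published accuracy.

## Training and inference

AdamW (decoupled weight decay 0.01) on the compound loss. The full-scale
schedule mirrors the published settings (2D: 400 epochs, batch 8, lr 1e-4;
3D: 1000 epochs, batch 2, patches 128×128×64, 250 patches/epoch). The
*desk* profile is the package's CPU-scale study condition: 64×64 phantoms
(2D) or 32×32×16 volumes (3D), a 4-sample training set, at most 600
optimizer steps, lr 1e-3 (the conventional Adam default, appropriate for
tiny models on short schedules), and an early stop once train foreground
DSC passes 0.98 (2D) / 0.92 (3D). Flip augmentation exists but is off in
the desk profile, whose purpose is overfit verification. Problem sizes
were chosen so the whole pipeline — generation, training, inference,
evaluation — completes in minutes on one CPU.

3D training samples patches with a configurable foreground bias (default
0.5); at desk scale the patch equals the volume because in-plane extents
must stay divisible by 32. Inference pads inputs to legality with edge
values and crops the output; 3D uses sliding windows with 0.5 overlap and
logit averaging, and a window covering the padded volume reduces exactly
to a single forward pass. Argmax ties resolve to the lowest class index.

Checkpoints are `.npz` archives carrying weights, batch-norm running
statistics, optimizer moments and the full training configuration as
embedded JSON, so a checkpoint alone reconstructs the model; training is
resumable with identical optimizer-state semantics.

## Known limitations

* The FFT convolution path introduces ~1e-6 relative float32 rounding
  differences versus the tap loop; irrelevant for training, visible only
  to bit-exactness comparisons (which therefore pin one path).
* Batch norm with batch sizes of 2–4 (desk profile) has noisy statistics;
  the profiles were sized with this in mind.
* The mirror-decoder comparator is a generic symmetric U-decoder, not a
  re-implementation of any specific published decoder; it supports the
  qualitative parameter comparison only.
* No distributed or mixed-precision training, no DICOM ingestion.
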