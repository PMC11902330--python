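# Methods

This note records the models, conventions and design choices behind
`gpcyolo`, at the level of detail a maintainer needs to trust or change
them.

## The detector

The network is an anchor-free single-stage detector of the YOLOv8n family
(width multiple 0.25, depth multiple 0.33), specialized to three-class
fruit-maturity detection (`0 = ripe`, `1 = semi-ripe`, `2 = unripe`) and
made light through four substitutions:

1. **GSConv downsampling.** Every stride-2 standard convolution except the
   stem — four in the backbone, two in the neck — is replaced by GSConv: a
   dense convolution producing half the output channels, a 5×5 depthwise
   convolution deriving the other half from them, and a two-group channel
   interleave. Its multiply–accumulate cost relative to dense convolution
   is exactly `(C1+1)/(2·C1)`, approaching one half as the input width
   grows.
2. **C2f-PC feature blocks.** Inside every C2f block, each bottleneck's two
   3×3 dense convolutions become *partial* convolutions: a 3×3 convolution
   over the first quarter of the channels (no norm, no bias, no
   activation), with the remaining channels passed through untouched.
   At the default quarter ratio this is 1/16 of the dense cost.
3. **A reduced-width cross-scale fusion (CCFF) neck.** The PAN neck is
   replaced by the RT-DETR-style convolutional cross-scale fusion: 1×1
   projections of the stride-16 and stride-32 backbone features down to the
   common neck width, a top-down path and a bottom-up path whose fusion
   blocks are C2f-PC and whose every convolution (projections, laterals,
   stride-2 downsamples) is a GSConv. All neck modules are capped at a
   nominal width of 256 channels — 64 real channels at the 0.25 width
   multiple. The stride-8 input is already 64 channels wide, so it needs
   no projection.
4. **SimAM attention** on each of the three neck outputs, immediately
   before the head. Each activation is reweighted by
   `sigmoid((x−μ)²/(4(σ²+λ)) + 0.5)` with per-channel spatial statistics
   (variance over `HW−1`) and `λ = 1e-4`. The stage has no weights, so it
   never changes a parameter count; 1×1 feature maps pass through
   unchanged since no variance is defined.

The head is the stock decoupled anchor-free Detect: per scale, two 3×3
conv stems each for the box and class branches, a 64-bin (4×16)
distribution-focal box output and an `nc`-way class output, at strides
8/16/32. The 16 weights of the frozen distribution-focal projection are
included in parameter counts, matching common model-summary conventions.

Wiring that figures alone under-determine (exact neck arrangement, the
depthwise kernel inside GSConv, norm placement in partial convolutions)
was resolved by treating the published per-variant parameter counts as
exact anchors; the configuration shipped here is the unique one in the
searched design space that reproduces all four counts integer-exactly
(3,011,433 / 2,731,833 / 1,843,737 / 1,206,649 at nc = 3).

## Profiling conventions

`profile_flops` propagates feature-map shapes through the layer DAG and
sums per-layer costs under an op-cost model chosen to match how
whole-model GFLOPs are customarily reported for this family of networks:

* convolutions and linear maps: 2 FLOPs per multiply–accumulate
  (plus the bias add where a true bias exists);
* batch normalization, counted unfused: 4 FLOPs per output element;
* SiLU activation: 6 FLOPs per element (a sigmoid and a product);
* pooling, upsampling, concatenation, attention: not counted.

Under this convention the baseline profiles at 8.22 GFLOPs and the full
lightweight model at 4.47 GFLOPs for a 640×640 input (reported to one
decimal as 8.2 and 4.5). The per-block convolution components are
cross-checked in the test suite against the closed-form cost laws in
`gpcyolo.flops`, which use exact integer/rational arithmetic.

`serialized_size_mb` is the float16 export size (2 bytes per weight);
checkpoints embed the full model config and a format version, and refuse
truncated or mismatched files.

## Losses

Box regression uses EIoU:

    L_EIoU = (1 − IoU) + ρ²(b, b_gt)/(w_c² + h_c²)
           + (w − w_gt)²/w_c² + (h − h_gt)²/h_c²

where `(w_c, h_c)` is the smallest enclosing box and ρ the center
distance. CIoU (aspect-ratio penalty `αv` with `α = v/((1−IoU)+v)`
detached, defined as 0 at the IoU = 1, v = 0 singularity) is available
for comparison. `ε = 1e-7` is added to every denominator so degenerate
boxes yield finite values rather than division failures. Losses are
defined per pair; the training loop performs the batch reduction.

The composite training loss is `7.5·box + 0.5·cls + 1.5·dfl`:
binary cross-entropy with task-aligned soft targets for classification
(normalized by the total target score), the mean pairwise EIoU over
assigned anchors for the box term, and the two-bin cross-entropy
distribution-focal term for the discretized box edges. Assignment is
task-aligned (top-10 by `score^0.5 · IoU^6` among anchors whose center
lies inside the box; contested anchors go to the highest-overlap box).

## NumPy backend

The network, its gradients and the training loop run on a compact
reverse-mode autodiff engine over float32 NumPy arrays (`gpcyolo.nn`).
Convolution is im2col + batched GEMM forward and backward; every backward
rule is hand-written and verified against central finite differences in
the test suite. Two conventions worth knowing:

* `maximum`/`minimum` split the gradient evenly at exact ties, so
  symmetric expressions such as IoU are stationary at coincident boxes
  (the EIoU gradient at a perfect prediction is exactly zero).
* Batch-norm running statistics are bias-corrected exponential averages
  (momentum 0.03, divided by `1 − (1−m)^t` at eval time), and the
  training loop finishes with a "precise-BN" recalibration pass: running
  statistics are reset and recomputed from the training batches under the
  final weights. With the long schedules typical of full training this is
  a no-op in effect; with the short schedules used in tests it is what
  makes eval-mode inference consistent with the trained weights.

Optimization is SGD (momentum 0.937, weight decay 5e-4 on convolution
kernels only, never on norm scales or biases), learning rate decaying
linearly from 0.01 to 0.0001. Warm-up is omitted — the published protocol
specifies only the initial rate, momentum, decay, batch 16, 640 px and
300 epochs, which are the config defaults.

## Synthetic scenes

The original 1249-image orchard dataset is not publicly deposited, so a
synthetic generator (`gpcyolo.data.generate_scenes`) stands in for it.
It emulates the properties that drive the pipeline: three maturity
classes distinguished chiefly by color (red/orange/green bands with hue
jitter), a 12:5:10 class imbalance, overlapping fruit clusters
(neighbor placement with probability 0.3), partial leaf/branch occluders
(probability 0.3), global illumination jitter (±30%), object scales of
3.5–11% of the frame, and pixel-accurate labels for every rendered fruit
— deliberately including no unlabeled distant background fruit. It does
*not* attempt photorealistic texture, specular highlights, depth of
field or true foliage geometry, so passing tests demonstrate that the
pipeline is correct and trainable, not that field accuracy on real
orchard imagery is reproduced.

The offline augmentation follows the published recipe exactly:
minority-class images gain +90°/+180°/+270° rotations (so 304 minority
images become 1216), then the entire set — originals and rotations — is
mirrored horizontally, giving `(N − M + 4M)·2` images (4322 from 1249),
and the 8:1:1 split uses floor/floor/remainder rounding, the unique rule
that yields 3457/432/433. The split is an unstratified seeded shuffle;
the published sizes do not depend on stratification.

## Problem sizes in the test suite

Architecture and profiling checks run at the full 640×640 configuration
(they are analytic and cheap). Gradient and loss unit tests use 64-pixel
inputs. The end-to-end overfitting check trains the full detector on 8
synthetic scenes at 320 px for 50 epochs (batch 8) and requires
mAP50 ≥ 0.9 on those same images — small enough to memorize quickly,
large enough to exercise assignment, both loss branches, checkpointing
and decoding. These sizes are the package's CI configuration, chosen so
the whole suite runs on a single CPU in minutes.

## Known limitations

* The backend is single-threaded NumPy; full-scale 640-px training at
  the published 300-epoch schedule is out of its intended use. The
  training loop exists to validate the method end-to-end and for
  small-scale experiments.
* Detection accuracy figures from the original study (P/R/mAP on the
  authors' tomato photographs) require their non-deposited dataset and
  are not reproduced — only the architecture, cost, and pipeline
  arithmetic are.
* Rotated boxes, mosaic/mixup augmentation, and alternative IoU variants
  (GIoU/DIoU/SIoU) are out of scope.
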