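# Methods

## Detector family

The baseline is the standard YOLOv8n: a C2f backbone (width multiple 0.25,
depth multiple 0.33), SPPF, an FPN top-down + PAN bottom-up neck, and a
decoupled anchor-free head with a 16-bin distribution over each box side
(DFL). With one class the head's class branch width is max(ch_P3, 1) and the
box branch width is max(16, ch_P3/4, 64). Parameter reports count every
parameter tensor, including the frozen 16-weight DFL expectation projection,
which is how whole-model budgets are conventionally quoted; the baseline
then counts 3,011,043 parameters (3,011,027 trainable).

Three flags modify the baseline independently:

* `mobilevit` replaces the backbone with a MobileViT-style stem: one 3×3
  stride-2 convolution (3→16), an MV2 inverted residual (16→16), a stride-2
  MV2 stage (16→24, 24→24), then three stages that pair a stride-2 MV2 with
  a MobileViT block — channels 36/60/72 at P3/P4/P5, transformer widths
  64/76/80, depths 2/3/3, 4 heads, MLP ratio 2, 2×2 patches, MV2 expansion
  2 — and an SPPF at P5. The neck widths shrink to 40/40/96. The patch
  unfold keeps patches in row-major grid order and pixels in row-major
  order within each patch; fold is its exact inverse, and both raise on
  non-tiling shapes rather than padding silently.
* `lsk` inserts one large-selective-kernel block after the P3-scale
  processing layer of the neck. The block follows the reference LSK design:
  a 5×5 depthwise convolution, a 7×7 depthwise convolution with dilation 3
  (effective 23×23), two 1×1 projections to C/2, per-pixel mean and max
  pooling across channels, a 7×7 convolution from the 2 pooled maps to one
  sigmoid mask per kernel, a masked sum, a 1×1 fusion back to C, and an
  elementwise product with the input. All its convolutions carry biases and
  no normalisation, so its parameter count is exactly 1.5C² + 78C + 198.
* `gsconv` replaces the two dense stride-2 convolutions of the PAN
  downsampling path. GSConv computes half the output channels with a dense
  k×k convolution and the other half with a 5×5 depthwise convolution of
  the first half, concatenates, and interleaves the halves with a
  group-2 channel shuffle.

### Width calibration

The published ablation fixes the baseline and the two standard-backbone
single-modification budgets exactly (3,011,043 / +11,334 for LSK at C=64 /
−89,760 for GSConv at C=64,128 — the latter is what pins the GSConv
depthwise kernel to 5×5). The MobileViT-backbone widths are not published,
so they were calibrated once against the printed budgets: achievable totals
are congruence-constrained (mod 4) by the block structure, which forces the
P3/P4 neck widths to (40, 40); an exact meet-in-the-middle search over stage
widths and transformer dimensions then selected, among all configurations
whose full-model count is exactly 1,173,429, the one whose FLOPs best match
the printed 5.40 G / 5.30 G pair and whose widths grow monotonically. The
printed intermediate ablation rows are mutually inconsistent at the ~0.1%
level (no single architecture can satisfy all four MobileViT rows at once),
so the backbone-only variant lands at 1,181,111 (−196, 0.017%) and the two
combination rows carry residuals of similar size; the full model and the
baseline are exact.

### FLOP accounting

`count_flops` attributes, per forward pass: 2 ops per multiply-accumulate in
convolutions and linear layers, 1 op per bias add, 4 per element for an
affine batch norm, 2 per element for an activation, k² per output element
for max pooling, 7 per element for layer norm. Attention tensor products
(QKᵀ and AV) and softmax are not attributed, matching the layer-hook
convention of the profilers commonly used to report detector FLOPs (and the
only convention under which a transformer backbone at the stride-8 scale
can be reported below the convolutional baseline). Counts are closed-form
functions of the architecture and input size, so they are bit-reproducible.

## Tensor core

Training and inference run on a small reverse-mode autodiff core over
float32 numpy arrays: NCHW convolutions (strided/dilated/grouped) via
im2col with an explicit col2im adjoint, max pooling by argmax scatter,
nearest-neighbour upsampling, batch norm (batch statistics with gradients in
training, running stats at eval; eps 1e-3, EMA momentum 0.03 as in the YOLO
family), layer norm, multi-head self-attention composed from linear maps and
a fused softmax, and the pointwise ops needed by IoU losses (min/max/clip/
atan). Gradients are verified against central finite differences and conv
forward against scipy's correlate in the test suite.

## Training

The loss is the composition the architecture inherits: task-aligned
assignment (alignment metric s^0.5·IoU^6 over anchors whose centre lies in
the box, top-10 per target, ties to the best metric), BCE on class logits
against soft targets normalised per ground-truth box, complete-IoU on
assigned boxes, and distribution focal loss on the two integer bin
neighbours of each target distance, weighted 7.5/0.5/1.5. The optimizer is
SGD with lr 0.01, momentum 0.937, weight decay 0.0005, batch size 4, 300
epochs by default, with a 3-epoch linear warmup and a global gradient-norm
clip at 10 added for stability of the from-scratch CPU runs (both
documented knobs of `TrainConfig`). Desk-scale tests train at 64×64 input
on a handful of synthetic scenes — enough to demonstrate loss descent and
memorization (mAP→100% on a 4-image set in ~200 epochs) within minutes on
one CPU; these sizes are a deliberate scaling-down, and nothing about
orchard-scale accuracy should be read into them.

## Inference

Boxes decode as the softmax expectation of each 16-bin side distribution,
scaled by the stride around cell centres; class scores are sigmoid logits.
Greedy NMS uses confidence 0.25 and IoU 0.45 by default (both configurable)
with a deterministic (score, area, index) tie-break, making the output
invariant to input ordering. At inference the letterbox parameters recorded
during preprocessing are inverted so boxes and picking points are reported
in original image coordinates.

## Synthetic scenes

The generator emulates the statistics of orchard captures: 640×480 frames; a
low-frequency textured green-brown background; 4–12 quasi-elliptical fruit
of 12–26 px radius with radial shading, a ripeness-dependent hue and a
specular spot; 6–16 elongated leaf occluders biased to land near fruit;
a global illumination factor in [0.7, 1.3]. A fruit is annotated if at least
25% of its pixels survive later-drawn fruit and opaque leaves (threshold
configurable); the box is the full-extent ellipse hull clipped to the frame,
as a human annotator boxes a partially hidden fruit. Everything derives from
one integer seed, so scenes are bit-reproducible. The split arithmetic
partitions n images 8:1:1 by largest-remainder rounding and expands every
split threefold with augmented copies (brightness ±30%, translation ±10%,
mirror, rotation ±15° — ranges are package choices), reproducing the
930 → 2232/279/279 bookkeeping; a `augment_val_test=False` switch restricts
the expansion to the training split, which is the methodologically safer
setting for new work. What the generator does **not** model: real foliage
texture and colour statistics, perspective and bokeh, fruit size/ripeness
distributions of an actual orchard, or correlated lighting. Tests that pass
on these scenes validate the pipeline's mechanics, not field accuracy.

## 3D localization

A detection's picking point is its box centre. Deprojection uses the pinhole
model with depth in millimetres (depth-camera convention; calibration
translations are converted from metres when needed, and units are recorded
in the calibration file). The hand-eye calibration — an eye-to-hand
quaternion (qw, qx, qy, qz), normalised on input, plus translation — is
expanded to the standard rotation matrix and assembled into a 4×4 affine
transform applied to homogeneous coordinates; frame tags ("camera"/"base")
are enforced so points cannot be transformed twice. A non-positive depth at
the centre pixel falls back to the median of valid readings in the 5×5
surrounding patch (configurable off); detections with no valid depth are
returned in a separate failure list, never dropped silently. A simulated
RGB-D camera (projection + disc-shaped depth splats, nearer fruit
overwriting farther) provides the render-then-invert oracle: with exact
depth the chain recovers base-frame positions to ~1e-13 mm; with Gaussian
depth noise σ the axial mean absolute error approaches σ·√(2/π), the folded
normal mean, while lateral errors are attenuated by pixel-offset/focal
ratios. Physical positioning accuracy of a real arm-camera rig is
hardware-bound and out of scope; only the error statistics (per-axis mean
absolute error and standard error s/√n, with the sample standard deviation)
are implemented and unit-tested.

## Numerical and design choices

* Normalisation/activation inside all blocks follows the YOLOv8 convention
  (batch norm + SiLU); the MobileViT transformer uses pre-norm layers with
  SiLU MLPs; the 1×1 expansion into the transformer carries no norm, bias
  or activation.
* mAP is reported at IoU 0.5 (the community's single-number convention),
  configurable; both the all-point interpolated AP (default) and the raw
  precision staircase over recall increments are available.
* Precision and recall are defined as 0 when their denominator is 0.
* AP matching is greedy in score order with deterministic tie-breaks
  (score, area, index); each ground-truth box matches at most once.
* The LSK fusion convolution is 1×1 and the GSConv depthwise kernel is 5×5;
  both follow from matching the published parameter deltas exactly.
* Model "size (MB)" depends on storage precision, so reports carry both
  fp32 and fp16 figures (the fp16 figure corresponds to the published
  2.52 MB full-model size).
* Checkpoints are a single `.npz` of named weight arrays plus the YAML
  config that rebuilds the architecture.

## Known limitations

* CPU-only numpy training is orders of magnitude slower than a GPU
  framework; the package targets architectural fidelity and desk-scale
  verification, not production training.
* Batch-norm statistics are updated per batch without cross-image sync
  subtleties; very small batches at eval-sensitive layers can make early
  evaluations noisy.
* The synthetic scenes are deliberately simple (see above); mAP measured on
  them does not transfer to field imagery.
* The hand-eye calibration is consumed, not estimated; marker-based
  calibration belongs to the robot stack.
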