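# Methods

## The model family

MIFNet is a three-stage 2D CNN for 50x50 single-channel CT patches.  Each
stage is: a 1x1 *scaling* convolution (-> BN -> ReLU) that sets the stage
width `w_s` ((16, 32, 64) by default, doubling as the feature map halves);
one *MIF block*; and a ceil-mode 2x2 stride-2 pooling (max after stage 1,
average after stages 2 and 3) followed by dropout (rates 0.1/0.2/0.3).  An
MIF block holds three parallel branches, each a chain of `k` *mini-blocks*:

    Conv 1x1 (-> b_s) -> BN -> ReLU -> Conv 3x3, 'same', g groups (-> u) -> BN -> ReLU

with bottleneck widths `b_s = (4, 8, 16)` and base group counts
`g = (4, 4, 4)`.  After every mini-block the branches exchange information
by *interleaved channel fusion*: branch `i`'s next input is the channel
concatenation of the outputs of branches `i ... i+C-1 (mod 3)`.  `C = 1`
disables mixing; `C = 3` makes all branches identical.  Identity shortcuts
from the block input are added (before the mini-block's closing ReLU)
wherever the 3x3 output width equals the block input width.  The nominal
depth counts convolution layers only: `3 + 6k + 1` (three scaling layers,
two convs per mini-block x three stages, one classifier), so
k = 1 ... 7 gives the preset ladder 10, 22, 28, 34, 40, 46.

### Fusion topologies

The published description of what happens to the *widths* under repeated
concatenation is ambiguous, and the printed complexity ladder is the only
ground truth for the exact topology.  The package therefore implements two
schemes behind one switch (`NetworkConfig.fusion_mode`):

* **`growth`** (default, calibrated): each mini-block's 3x3 output width is
  matched to its fused input, so per-branch channels grow geometrically —
  `n_j = w_s * C^(j-1)`.  The 3x3 group count scales with that width
  (keeping the per-group width constant) and is capped by divisibility with
  the bottleneck width.  The block output is the element-wise *integration*
  (sum) of the three branches' fused outputs — the "integrated network"
  reading of the ensemble — and the classification head applies a global
  average pool before the dense layer.  This is the variant, out of ~400
  systematically enumerated reconstructions (width/bottleneck/group growth
  schedules x branch-merge rules x head types x FLOP conventions), that
  reproduces the headline figure (0.7 M parameters at depth 40, to the
  printed decimal) with the best overall fit to the remaining ladder.
* **`reduced`**: widths stay at `w_s` throughout, the block output is the
  channel concatenation of the three branch outputs (3 `w_s`), and the 7x7
  map is flattened into the classifier.  This is the minimal literal
  reading of the block diagram; it yields a ~5x smaller network (depth 40:
  ~0.13 M parameters) and is kept as a first-class configuration.

Calibration residuals (growth mode, defaults): parameters in millions per
depth 10/22/28/34/40/46 are 0.020 / 0.086 / 0.169 / 0.336 / 0.670 / 1.336
against the published 0.017 / 0.091 / 0.18 / 0.356 / 0.70 / 1.394 — the
depth-40 headline agrees at one printed decimal, other rows deviate by
4–13 %.  FLOPs run ~15–19 % above the published column under the frozen
convention below.  The per-cell acceptance tests compare at printed
precision and are left failing where the reconstruction deviates, rather
than loosened; the residuals indicate the original implementation contains
detail that the text and tables do not pin down.  The doubled-width variant
(`mifnet46_wide`) doubles the *stage widths* to (32, 64, 128) with
bottlenecks unchanged; among the three doubling interpretations this is the
one that tracks the published wide-ladder parameter column (within
1.5–5.6 %), so it was adopted.

### Geometry calculus

Output size `v' = floor((v + 2p - k)/s) + 1` for convolutions and
`ceil(...) + 1` for the poolings — ceil mode is forced by the published
25 -> 13 transition.  The jump (accumulated stride) multiplies:
`c' = c * s`.  The receptive field grows by `(k - 1) * c` per layer with
`r = 1` for the empty prefix; two stacked 3x3 stride-1 convolutions give
r = 5.  The propagation is verified exactly against a gradient-support
oracle: backpropagate a single interior output pixel through a toy
all-ones network and measure the nonzero input footprint.

### Complexity conventions

Parameters: conv `k^2 * c_in * c_out / g` (bias-free — batch norm absorbs
the bias), BN `2c` (scale and shift), dense `c_in * c_out + c_out`;
everything else zero.  FLOPs: one multiply-accumulate per unit, convolution
and dense layers only; BN, activations and pooling count zero.  The
MAC-vs-2xMAC switch was calibrated once against the published ladder
(MAC = 1 fits better) and frozen.  Serialized size is 4 bytes (float32) per
parameter, reported in MB = 2^20 bytes; the published parameter/size pairs
are mutually consistent under exactly this convention, which is why it is
fixed.

## Runtime

The runnable network is derived from the same symbolic layer graph the
analyzer counts, executed by a small NumPy engine (grouped conv via im2col,
batch norm with running statistics, ceil-mode pooling, inverted dropout,
Xavier-uniform init, softmax cross-entropy with fused gradient, Adam /
SGD-momentum / RMSprop).  All gradients are validated against central
finite differences (relative error < 1e-8 on a mixed-layer network).
Because the regime trains few epochs on small sets, the exponential running
statistics of batch norm lag the final weights; after the last epoch the
statistics are *finalized* by averaging batch moments over the training set
with dropout disabled — the standard finalization step, without which
inference-mode accuracy is unrelated to training accuracy.  Determinism:
weight init and dropout derive from the network seed, batch order from the
training seed; identical (data, seeds, optimizer) reproduce histories and
metrics bit for bit.  Ties in the argmax prediction go to the positive
(nodule) class.

## Preprocessing

Annotated candidates arrive as world-frame millimetre coordinates; voxel
indices are `round((world - origin)/spacing)` per axis (nearest-integer —
the round trip is within spacing/2 by construction).  Hounsfield units are
clipped to [-1000, 400] — air to soft tissue/bone, the common lung-CT
window, chosen because the source text says only "rescaled" — and mapped
affinely to [0, 1].  Patches are 2D axial 50x50 crops at the annotation's
z slice, zero-padded at volume borders.  Class rebalancing keeps 5
uniformly drawn negatives per positive (one nodule in six images) and
augments each positive with its 90/180/270 degree rotations — axis-aligned
turns avoid interpolation artifacts; the published rotation angles are
unstated.  The train fraction defaults to 0.8, matching the published
train/test proportions; the split is a seeded shuffle.

## Synthetic data

`make_synthetic_scan` writes MetaImage volumes of Gaussian noise around
-800 HU (lung-like) with additive bright spheroids (~+800 HU above
background, i.e. soft-tissue attenuation at the center), one positive
annotation per spheroid and negatives sampled at least two radii away.
`make_patch_dataset` emits balanced 50x50 sets where positives carry a
centered disc of radius 4–12 px and amplitude `separation * noise_sd`
(defaults 8 x 0.05, verified >95 % separable by a pixel-mean threshold
classifier before any network sees it) and negatives carry nothing or an
off-center quarter-amplitude distractor; `separation = 0` is an exact null.
These fixtures exercise file formats, geometry and learnability — they do
not model CT texture, partial-volume effects, vessels or scanner physics,
so passing the learnability tests says the training machinery works, not
that the architecture separates real nodules.

## Problem sizes

Desk-scale defaults keep every test cheap: training sanity checks use the
smallest preset (`mifnet10`, ~20 k parameters) for 5 epochs on 160 training
patches (~half a minute on one CPU); the optimizer comparison uses 2 epochs
per optimizer; complexity and geometry checks are analytic and run in
milliseconds.  The full pipeline scales to the larger presets unchanged —
only wall-clock time grows.

## Known limitations

* The growth topology is a calibrated reconstruction; only the headline
  parameter count is reproduced at printed precision (residuals above).
* Training is CPU NumPy: fine for the desk-scale presets, slow for
  `mifnet46_wide` on large datasets.
* No lung segmentation, slice-thickness filtering, 3D context, transfer
  learning or learning-rate schedules — out of scope by design; a constant
  learning rate is used because only an initial rate is published.
* Metrics with zero denominators are reported as undefined (`None`), not 0,
  so degenerate evaluations are visible rather than silently optimistic.
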