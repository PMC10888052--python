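# Methods

## Problem setting

Multi-sequence MRI brain-tumor segmentation labels each voxel of a
co-registered, skull-stripped 4-sequence volume (T1, T1ce, T2, FLAIR) with
one of four classes: background, necrotic/non-enhancing core (NCR),
peritumoral edema (ED), and enhancing tumor (ET). Supervision and
evaluation happen on three *nested* binary sub-regions: ET, tumor core
TC = ET ∪ NCR, and whole tumor WT = TC ∪ ED. The model emits three
independent sigmoid probability maps, one per sub-region; predicted masks
are the probabilities thresholded at 0.5 with ties mapping to foreground,
and are *not* forced to nest unless the `nested` post-processing flag is
set (off by default, so raw model behavior stays observable).

## Architecture

`ModelConfig` fully describes the network; every ablation variant is a
config edit, never a code edit. The components:

* **Stem** — 3×3×3 conv → GroupNorm, residual-added to a 1×1×1 projection
  of the input, then ELU. The projection exists because a literal residual
  add is shape-inconsistent when the stem widens 4 channels to `stem_channels`.
* **MFP paths** — path *i* trilinearly downsamples the raw input by 1/2^i
  and applies *i* DSPC blocks whose widths ramp geometrically from the
  input channel count to the path's target width (endpoints exact). The
  target width equals the encoder stream width at that level, so the
  encoder concatenation doubles channels. Paths are mutually independent.
* **Encoder / decoder** — as in the README; all resolution changes are
  trilinear interpolation with half-pixel-center ("align_corners=False")
  semantics, chosen because the scale-factor interpretation is exact for
  powers of two and symmetric between the down and up paths. The deepest
  decoder step consumes the deepest encoder output directly (there is no
  separate bottleneck block).
* **DSPC block** — depthwise 3×3×3 conv (the standard lightweight choice)
  → GroupNorm → Att_1 → ELU → pointwise 1×1×1 conv → GroupNorm → ELU →
  residual add → Att_2. Canonically Att_1 is spatial attention and Att_2
  channel attention; both slots accept any of
  {none, spatial, channel, coordinate, cbam}. When in/out widths differ the
  residual identity path is a 1×1×1 projection. Convolutions immediately
  followed by GroupNorm carry no bias (the normalization absorbs it; this
  convention matters for reproducible parameter counts).
* **Skip attention (HCA)** — channel attention (configurable) applied to
  the lateral feature before each concatenation, on both the MFP→encoder
  and encoder→decoder skips.

Attention designs follow the common conventions: channel attention is
global-average-pool → two-layer bottleneck MLP (ReLU inside, reduction 4
at tiny widths, 16 at full widths, clamped to the channel count) → sigmoid
gates; spatial attention concatenates channel-mean and channel-max maps
and convolves them (default kernel 7³, replicate padding so a constant
field gets a constant gate); coordinate attention pools per spatial axis,
passes the three profiles through a shared bottleneck, and applies one
sigmoid gate field per axis. Every variant ends in a sigmoid
multiplication, so all are elementwise contractions.

GroupNorm uses the largest divisor of the channel count that is ≤ 8.
ELU uses α = 1. Weight initialization is Kaiming fan-in from a single
seeded generator per model, so identical seeds build identical networks.

## Numerical core

No deep-learning framework is used. `nlinet.nn` is a reverse-mode
autodiff engine on float32 numpy arrays: grouped 3D convolution via
im2col + einsum (with a pure-matmul fast path for 1×1×1), fused GroupNorm,
separable trilinear resampling with exact scatter-add adjoints, and the
usual elementwise/reduction ops, each defining its own vector-Jacobian
product. AdamW implements decoupled weight decay. Gradient correctness is
tested against central differences for every op.

## Losses

* Dice: per-region soft overlap with smoothing ε = 1e-5 added to numerator
  and denominator so an empty region contributes loss 0 rather than 0/0.
* Weighted cross-entropy: implemented exactly in its positive-class-only
  form, with probabilities clamped at 1e-7 before the log. The weight
  w_k = |WT|/|k| is computed per sample from the ground truth (batch size
  is 1 in the reference protocol); empty regions get w_k = 0. Because the
  negative-class term is absent, WCE alone is minimized by predicting 1
  everywhere — the Dice term supplies the false-positive penalty, and the
  test suite asserts both the degeneracy and its rescue. A `full_bce` flag
  adds the (1−y)ln(1−p) term for experimentation (off by default).
* Loss menu for training: `dice` (Dice only), `dice_ce` (Dice + unweighted
  per-region BCE with both classes — the conventional baseline), and
  `dice_wce` (the default combo). The `dice_ce` reading of the baseline is
  an assumption; a label-wise softmax formulation would also be defensible.

## Metrics

IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN) from exact voxel confusion
counts. HD95 extracts mask surfaces (a mask voxel with a 6-neighbor
outside the mask; the volume border counts as outside), computes both
directed surface-distance sets with Euclidean distance transforms, takes
each set's 95th percentile (linear interpolation between order statistics
— nearest-rank differs on tiny surfaces, hence the explicit choice), and
aggregates with max; a `pooled` flag switches to the pooled-percentile
alternative. Spacing scales all axes; default (1,1,1) voxel units.

Degenerate conventions, all flagged in `MetricsReport` so tables can
exclude them: both masks empty → IoU = Dice = 1, HD95 = 0; exactly one
empty → HD95 = the image diagonal. HD95 means skip flagged regions.
An all-pairs brute-force surface-distance oracle validates the
distance-transform implementation to 1e-9 on random small masks.

## Data pipeline

Cases live one directory each (`<case>_<seq>.nii.gz`, `<case>_seg.nii.gz`);
the on-disk enhancing-tumor code 4 is remapped to the internal contiguous
code 3, and volumes are reoriented to canonical axis order. Z-scoring is
per volume over nonzero (brain) voxels — the voxel set is a choice, since
per-dataset or all-voxel variants exist — and background stays 0.
Training augmentation order: random axis flips (p = 0.5 each) → random
in-plane rotation in ±15° (a small, minimally destructive range; trilinear
for images, nearest for labels so codes survive) → pad-then-random-crop to
the target shape (192×192×128 at full scale, 32×32×16 in tests) → additive
Gaussian noise σ = 0.1 in z-scored units on images only. Validation and
test volumes are only center-cropped. Splits are a seeded shuffle into
7:1:2 with floor/floor/remainder sizes.

## Synthetic phantoms

The generator emulates the data contract, not the physics: a brain
ellipsoid on zero background with nested tumor ellipsoids (ET inside TC
inside WT, radius ratios 0.42 / 0.65 of the WT radius with ±20% per-axis
anisotropy), a per-sequence contrast table giving each tissue a distinct
offset on at least one channel (ET bright on the T1ce-like channel, ED on
the FLAIR-like channel), and Gaussian noise inside the brain only (so the
z-score foreground convention holds). Generation asserts that every
tissue pair is separated by ≥ 3× the noise σ on some channel, and default
radii make |ET|/|WT| < 0.2, so the sub-region weighting is exercised
meaningfully. What passing tests on phantoms show: the architecture,
losses, metrics, and pipeline are wired correctly and the model can fit a
learnable signal. What they do not show: segmentation quality on real
tumors, whose intensity statistics, shapes, and artifacts phantoms do not
model.

## Training

Defaults follow the reference protocol: AdamW, lr 1e-4, weight decay 1e-5,
batch size 1, 200 epochs, constant learning rate (no schedule is part of
the protocol; a cosine flag exists and is off). The best-validation-Dice
checkpoint is retained — best-checkpoint selection is a choice, early
stopping would be an alternative. A non-finite loss aborts with context.
The desk-scale test profile (10 training phantoms at 32×32×16, 20 epochs
= 200 optimizer steps) uses lr 3e-2: two hundred steps is three orders of
magnitude less optimization than the full protocol, and the full-scale
rate cannot leave initialization in that budget for any model; 3e-2 is the
conventional order of magnitude for a tiny model trained for hundreds of
steps. With it, held-out phantom mean Dice exceeds 0.99 in under a minute
of CPU time.

## Complexity accounting

Parameters and MACs are computed from the layer inventory, never a forward
pass. 1 MAC = one multiply + add; convolutions contribute kernel elements
× in-channels-per-group × out-channels × output voxels, linear layers
in × out × positions (1 for channel attention, axis lengths for coordinate
attention). GroupNorm, activations, gating multiplies, bias adds, and
interpolation are excluded — the dominant convention of FLOP counters, and
stated because the exclusions affect cross-paper comparability. The
analytic totals are tested to equal exhaustive enumeration of built
models' scalars for every attention variant.

The lightweight comparison's baseline is the identical topology with each
DSPC block replaced by one dense bias-free 3×3×3 convolution
(+ GroupNorm/ELU/residual) and all attention removed — the most literal
"original configuration". At the reference plan and 192×192×128 input this
yields a parameter ratio of 0.079 (2.24 M vs 28.4 M) and a MAC ratio of
0.110 (98.9 G vs 900 G); `nlinet count` and `scripts/acceptance.py` print
the ratios together with these assumptions. The ratios shift with the
channel plan and with what the baseline is taken to include, which is why
the report always states both.

## Known limitations

* CPU-only numpy execution: full-scale (192×192×128, 5-level) training is
  far outside this implementation's performance envelope; it is meant for
  desk-scale study and small volumes.
* No sliding-window inference, test-time augmentation, deep supervision,
  or multi-GPU support (out of scope by design).
* Phantom realism limits (above); reported phantom metrics say nothing
  quantitative about clinical data.
* The positive-only WCE term is kept verbatim for fidelity despite its
  standalone degeneracy.
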