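# Methods

This note records the operator's exact semantics, the free design
choices made where the published description leaves room, the numerical
conventions, what the synthetic generators do and do not emulate, and
the problem sizes the default test and reproduction runs use.

## Operator semantics

### Receptive-field attention branch (SCARF)

Given X ∈ ℝ^{B×C×H×W} and odd kernel size k (default 3):

1. **Context pooling** — average pooling with kernel k, stride equal to
   the module stride, padding k//2.  The pooling is count-normalised
   (border windows divide by the number of valid taps), so a constant
   map pools to itself and the attention grid aligns positionally with
   the feature grid: H' = ⌈H/stride⌉.
2. **Expansion** — a grouped 1×1 convolution C → C·k².  The grouping is
   configurable (`attention_groups`, must divide C) and defaults to C,
   one filter bank per channel; its bias is zero-initialised so the
   attention starts uniform (1/k² everywhere).
3. **Normalisation** — softmax over the k² axis after reshaping to
   (B, C, k², H', W').  The softmax axis is the receptive-field-sample
   axis, not space: each position distributes unit mass over the k²
   samples of *its own* window.
4. **Features** — a grouped k×k convolution C → C·k² with groups = C
   (each channel yields its own k² receptive-field samples, matching
   the C → C·k² bookkeeping), batch normalisation, ReLU (the published
   form writes an unspecified σ; ReLU is the conventional choice), and
   ECA channel recalibration over the C·k² channels.
5. **Fusion** — the weighted samples are placed into a (k·H' × k·W')
   mosaic in row-major order (sample u·k+v of cell (i, j) lands at
   pixel (i·k+u, j·k+v)) and a stride-k, k×k convolution C → C_out
   collapses exactly one mosaic cell per output position.  Channel
   mapping for C_in ≠ C_out happens in this fusion convolution.

ECA's adaptive width is t = ⌊|log₂(C)/γ + b/γ|⌋ forced odd with a floor
of 3, γ = 2, b = 1 (the constants of the cited channel-attention
design; C = 64 → 3, C = 256 → 5).  The 1-D convolution is bias-free and
zero-padded across the channel axis.

### Edge-enhancement branch (MEFE)

Per pyramid scale s_i (defaults (20, 18, 8) classification,
(18, 14, 8) detection, (20, 15, 8) segmentation — configurable, since
the published tuples could not be read unambiguously):
adaptive average pooling to s_i×s_i (clamped to the input size with a
warning when the feature map is smaller), 1×1 reduction to C/r
(r = 4 by default), a 3×3 depthwise + 1×1 pointwise pair, bilinear
upsampling (half-pixel centres, no corner alignment) back to (H, W);
then the high-pass step E_i = F_i − AvgPool₃ₓ₃(F_i) and the residual
refinement F̂_i = F_i + φ(E_i), with φ a two-layer bias-free
depthwise-separable stack with an interior ReLU.  All F̂_i concatenate
and a biased 1×1 convolution maps to C_out; stride > 1 is realised by a
final stride-sized average pooling.

Two conventions make the DC-kill invariant *exact* rather than
approximate: the 3×3 smoothing divides by the count of valid taps at
borders, and every spatial convolution in the branch uses replicate
padding and (except the final fusion) no bias.  A spatially constant
input therefore passes through the branch spatially constant, and its
edge response is identically zero.

### Fusion

Y = α·F_SCARF + (1−α)·F_MEFE with α = sigmoid(α_logit).  α_logit is a
single learnable scalar per operator instance (the published text
treats α as one weight; per-instance learning is the natural reading
for a plug-in module), initialised to the inverse sigmoid of
`alpha_init`.  α is confined to (0, 1) for every finite logit, and Y
lies elementwise on the segment between the branch outputs.

## Backbone integrations

* **ResNet-18** — the first 3×3 convolution of each of the eight
  BasicBlocks is replaced (eight replacements, matching channels and
  stride), leaving the stem, second convolutions, projections and head
  untouched; the downsampling schedule is unchanged by construction.
* **DeepLabV3-ResNet-50** — output stride 8 (stages 3 and 4 dilated),
  atrous pyramid rates (12, 24, 36) with an image-level pooling branch,
  no auxiliary classifier; the published 39.63M parameter figure is
  reproduced exactly (39,634,243) at 3 output classes.  Non-baseline
  variants replace the 3×3 convolution of the three final-stage
  bottleneck blocks — the Methods-level statement ("deep bottleneck
  layers"); a later passage mentions pyramid-head insertion instead,
  and the generic `replace_convs` hook covers that reading if wanted.
* **Detectors** — no detector architecture ships; `replace_convs`
  applies the same surgery to any model built on this layer system.

## Complexity conventions

Parameters are learnable scalars (conv/linear weights and biases, BN
affine pairs).  MACs count one multiply–add for convolution and linear
layers only, tallied during a shape-propagating forward pass;
normalisation, pooling and activations are excluded.  Under this
convention the 1000-class ResNet-18 measures 11,689,512 parameters and
1,814,073,344 MACs at 3×224×224 — the published 11.69M / 1.81G row —
so figures quoted as "FLOPs (G)" for these backbones are read as MACs.

Variant deltas are direction-level, not value-level: the branch
internals (attention grouping, reduction ratio, refiner depth) are
free parameters, so the printed variant magnitudes are not uniquely
determined.  With the defaults here the classifier deltas are
+1.5% / −31.8% / +10.0% (attention / edge / fused) against published
+1.4% / −30.7% / +36.7% — same signs and ordering, smaller fused
magnitude.  On the segmentation backbone the published table shows the
edge branch *adding* parameters (+4.2%) while cutting FLOPs; with the
default r = 4 the edge branch shrinks parameters there too, and the
published direction is recovered by a reduction-free branch (r = 1),
which the tests exercise explicitly.

## The autodiff substrate

No deep-learning framework is a dependency: `seafec.tensor` is a
reverse-mode tape over float32 NumPy arrays providing exactly the
primitives the operators need (grouped/strided/dilated convolution
implemented as one GEMM per kernel offset with the batch folded into
the contraction, count-normalised and adaptive poolings, bilinear
resampling as separable matrix products, batch normalisation, softmax,
fused cross-entropy).  Convolution forward/backward is verified against
loop-level enumeration and finite differences in the test suite.
Models are built from seeded `numpy.random.Generator`s (default seed
42), making rebuilds bit-identical; checkpoints round-trip through
`.npz` containers.

## Synthetic generators

The generators reproduce *structural* regimes, not photometric
statistics of field imagery:

* classification — green leaf backgrounds with either 3–6 near-circular
  blobs (radius 4–8% of the image) or 2–4 elongated streaks (length
  45–85%, thickness 5–8%); streaks cover more pixels than blobs by
  construction, which is the separable signal the smoke training fits.
  An optional blurred-halo mode smooths lesion edges.
* segmentation — soil background, 3–5 long crop blades, and weed blades
  drawn on top (intertwined boundaries); weed count is calibrated so
  the mean weed pixel share tracks the requested fraction within
  ±50%.  Masks use {0 background, 1 crop, 2 weed}; the pseudo-colour
  palette is black/red/green and round-trips exactly.
* detection — sparse (1–3 large) or dense (10–16 small, overlap
  permitted) lesion boxes, 0-based half-open coordinates, always inside
  the image.

The doubling policy draws one operation per copy from {rotation
(90°/180°/270°/±15°), crop 80–100%, scale 0.8–1.2, Gaussian blur
σ ∈ [0.5, 1.5], Gaussian noise σ = 8/255} — the published parameter
values are unstated, so these are conventional defaults — and
transforms masks (nearest-neighbour) and boxes (corner transform,
axis-aligned hull, clipping) consistently.  Splits are per class with
floor rounding, remainder to the training split, at 7:2:1
(classification/detection) and 6:2:2 (segmentation).

Passing tests on these fixtures demonstrate mechanism (shapes,
invariants, optimisability, metric correctness), not field accuracy:
none of the published benchmark accuracies are claimed or reproduced.

## Problem sizes and numerics

Default desk scale: 32×32 fixtures, 200-sample training set, batch 32,
Adam at lr 1e-3 (the published classification recipe), at most 30
epochs with early stop at training accuracy 1.0; all four classifier
variants fit the fixture in ≤10 epochs.  Attention normalisation is
asserted to 1e-5; the enumeration oracle for the attention branch to
1e-5 absolute on instances with C ≤ 4, H = W ≤ 6; DC-kill and the
pseudo-colour round-trip are exact.  Degenerate inputs: pyramid sizes
exceeding the feature map clamp (with a warning); zero-denominator
rates report 0 and are flagged; detection classes without ground truth
are excluded from the mean and flagged; equal detection scores keep
input order.

## Known limitations

* The fused operator's parameter growth is smaller than the published
  +36.7% because the branch internals are under-specified; only
  directions are reproduced.
* Published pool-size tuples are best-effort readings; they are
  configurable precisely because the source text is ambiguous.
* The autodiff substrate is CPU-only and single-threaded beyond BLAS;
  it is sized for desk-scale verification, not benchmark training.
* No pretrained weights, detector architecture, saliency maps, or
  transformer variants.
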