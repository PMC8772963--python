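# Methods

This note documents the models, procedures and numerical choices behind
`pemnet`: a desk-scale pectoral-muscle segmentation framework for MLO-view
mammograms built around a global channel-attention encoder–decoder, a
rule-based breast-extraction chain, a synthetic phantom generator with
exact ground truth, and a six-metric evaluation suite.

## The segmentation model

The network follows the Deeplabv3+ encoder–decoder pattern at output
stride 16. A strided stem reduces the input to 0.25 of its height and
width; a stack of convolutional stages with channel doubling (default
16→32→64→128, two 3×3 convolutions per stage, dilation 2 on stride-1
stages after the last downsampling) forms the encoder. Atrous spatial
pyramid pooling (ASPP) with a 1×1 branch, three dilated
depthwise-separable 3×3 branches (rates 6/12/18) and a global-image
pooling branch aggregates context on the final features. The decoder
upsamples ×4 (bilinear, half-pixel-centre convention), fuses a 1×1-projected
raw low-level skip from the first stage, applies one 3×3 fusion
convolution and a 1×1 classifier head, and restores full resolution with a
final bilinear ×4.

### Global channel attention (GCAM)

At each tapped stage `x` with `C_x` channels, global max pooling and
global average pooling produce a concatenated channel-attention vector

    M_cat^x = [GMP(M^x); GAP(M^x)]  ∈ R^{2C_x}   (GMP half first),

which a two-layer perceptron refines while scaling it to the next stage's
width:

    M_RCAMs^x = σ(W1 · ReLU(W2 · M_cat^x)),  hidden width h = max(1, round(2C_x/r)).

The refined vector multiplies elementwise into the next stage's
concatenated vector; refine/multiply repeats down the chain, and the final
vector reweights the channels of the last feature map directly, with no
further refinement. With channel doubling the final vector length
`2·C_{x+n-1}` equals the last stage's channel count, so the last
multiplication needs no parameters; non-doubling chains are rejected
unless a parameter-free split-and-average projection is explicitly
enabled.

Parameter cost per refined transition is `h·C + C'·h` with `C = 2C_x`,
`C' = 2C_{x+1}` — i.e. `(C/r)(C + C')` when `r` divides `C` — plus
`h + C'` biases when biases are enabled (they are off by default, so
measured budgets match the closed form exactly). `budget_chain` sums this
over the `n−1` refined transitions and is asserted, in tests, to equal
the measured parameter difference between the assembled model and its
attention-free twin.

Two symbols in the refinement formula are written with one activation
letter; here the hidden activation is a rectifier and the output a
logistic sigmoid (both configurable). The shrink rate defaults to `r = 8`.
The hidden width rounds half-to-even via Python's `round`.

### Pooled-vector normalisation (`normalize_taps`)

Large classification backbones batch-normalise their stage outputs, so
channel-attention modules in that setting pool O(1) statistics. The
desk-scale stacks here are normalisation-free and run on the raw 8-bit
intensity scale, which makes pooled maxima/means O(100) and lets the final
multiplicative attention scale channels very unevenly — measurably hurting
the attention model relative to its baseline. `normalize_taps` rescales
each pooled vector to unit RMS before it enters the chain, restoring the
conditioning that post-normalisation features would have. It is **on** in
the assembled network's default configuration and **off** in the
standalone functional API, whose primitives compose exactly as written
above. It adds no parameters and does not affect the identity-bypass or
budget properties.

### Initialisation and input scale

Weights are He-normal; the classifier head and each refinement MLP's
output layer are zero-initialised (an untrained model predicts all
background, and attention starts as a flat 0.5 gate rather than a
saturated random one). Images enter on the raw 8-bit scale (0–255, no
/255): under the short desk-scale training protocol (roughly 70 optimiser
steps) the larger feature scale is what lets the zero-initialised head
move logits by O(1); rescaled inputs train far more slowly at the same
learning rate. Per-block RNG streams (`Generator.spawn`) make shared
layers of the attention model and its baseline identical at equal seed,
which is what the shared-weight bypass test exploits.

## Training protocol

Pixelwise cross-entropy (optional class weights, off by default), Adam
(β = 0.9/0.999, the optimiser is this package's choice), minibatch 32,
initial learning rate 1e-4 multiplied by 0.5 after each completed
20-epoch period (epochs 21 and 41 are the first reduced ones), shuffling
every epoch, maximum 50 epochs by default. Everything is seeded; two runs
with the same data, configuration and seed reproduce losses and weights
bit for bit on CPU. The desk-scale study used throughout tests and the
acceptance script trains for 10 epochs on 200 phantoms of 128×128 pixels
and evaluates on 40 held-out phantoms — sizes chosen so the whole study
runs comfortably on one CPU core.

## Preprocessing chain

Orientation is detected by comparing non-zero pixel counts of the left
and right image halves (ties → left, no flip); right-oriented images are
mirrored so the pectoral wall sits on the left. Binarisation uses a fixed
threshold of 20 on the 8-bit scale with strict inequality (the convention
`> t`; the threshold applies to 8-bit values, not rescaled ones). The
largest connected component (8-connectivity by default; size ties resolve
to the first label in raster order) becomes the breast mask, a binary
opening with a disk of radius 5 px removes small bright objects
(labels, acquisition artefacts), and image and mask are cropped to the
mask's tight half-open bounding box. Pixels outside the frame count as
background for the morphological operations. All coordinates are 0-based,
row-major, half-open. Structuring element, connectivity and threshold are
exposed as configuration since only the threshold value is canonical.

View classification (MLO vs CC) is a small three-block CNN trained from
scratch on 64×64 resized crops (Adam, lr 3e-3, 30 epochs, minibatch 32) —
shorter schedules at lr 1e-3 underfit. The two views differ by the
presence of the pectoral wedge, which the classifier separates essentially
perfectly on phantoms.

## Phantom generator

Each phantom is a dark background, a bright breast half-ellipse anchored
to one lateral edge, and (in MLO view) a brighter pectoral wedge in the
top corner on the breast side. The wedge boundary is a quadratic Bézier
between its top-edge and chest-wall anchors; the curvature parameter
displaces the control point along the outward normal, so 0 gives a
straight muscle boundary and positive values a convex bow. The wedge is
rasterised row-by-row from the Bézier's horizontal extent, which keeps the
pixel count within ~1% of the analytic triangle area for straight
boundaries. Optional bright artefact disks (radius 1–4 px) sit in the
non-breast margin and Gaussian mass-like blobs inside the breast. Noise
(additive Gaussian, clipped to [0, 255]) is applied after geometry, so
the stored masks are exact; a right-sided phantom is the exact mirror of
the left-sided phantom with the same seed because all randomness is drawn
in the left-oriented frame.

Default intensities (background 6, breast 120, pectoral 190, noise σ 5)
keep the contrast ordering real MLO mammograms exhibit. Dataset-level
variability (`DEFAULT_MLO_RANGES`) spans both lateralities, wedge bases
0.30–0.55 of image height, reaches 0.20–0.45 of width, curvatures −0.10
to 0.20, breast/pectoral intensities 100–140/170–210, noise σ 3–8, up to
two masses and three artefacts per image.

What the phantoms do **not** emulate: fibroglandular texture, skin lines,
vessel structure, scanner-specific noise spectra, low-contrast or
ill-defined muscle boundaries, and anatomy outside the
half-ellipse-plus-wedge idealisation. Passing tests therefore demonstrate
that the implementation is correct and trainable under controlled
geometry, not that the trained weights transfer to clinical mammograms.

## Metrics and reporting

From pixel tallies TP/FP/FN/TN: Jaccard = TP/(TP+FP+FN), DSC =
2TP/(2TP+FP+FN), GPA = (TP+TN)/total, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP). Set-wise IoU and Jaccard are the same quantity
for one class; the *reported* IoU follows the common evaluator convention
of averaging the per-class IoU over target and background, which is why
reported IoU exceeds target-class Jaccard on imbalanced masks. GPA is
averaged over images by default (a pixel-pooled variant exists behind a
flag). Degenerate denominators score 1 when truth and prediction are both
empty for the class and 0 otherwise, with the metric name recorded in an
`undefined` set. Aggregation is the unweighted per-image mean within a
run and, across repeated runs, the mean and sample standard deviation
(ddof 1; a single run reports 0) of run means.

## Numerical choices

- Feature maps are channel-first, `(C, H, W)` / `(N, C, H, W)`.
- Convolution is im2col + matmul (cross-correlation); gradients are
  exercised against central finite differences in the test suite.
- Bilinear upsampling uses half-pixel centres with edge clamping; its
  backward pass is the exact adjoint.
- Prediction ties (equal class logits) resolve to class 0 (background).
- Max-pooling gradients split equally among tied maxima.
- Float32 for model parameters and activations; metric arithmetic in
  float64.

## Known limitations

- The attention chain requires channel-doubling stage lists unless the
  split-and-average projection is enabled; arbitrary tap patterns inside a
  stage are not supported.
- The CPU implementation is intended for desk-scale studies; large-image
  or large-backbone training is out of scope.
- The view classifier and segmentation models are validated on phantoms
  only; clinical deployment would require retraining and revalidation on
  real mammograms.
- DICOM support is read-only and normalises to 8-bit before processing.
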