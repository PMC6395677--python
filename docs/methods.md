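# Methods

## Problem and approach

The package measures choroidal thickness from macular OCT volumes.  A
volume is 25 parallel B-scans (nominally 456 rows x 760 columns, 8-bit),
240 um apart.  Two boundaries are needed per scan: Bruch's membrane (BM),
the bright thin band under the retinal pigment epithelium, and the lower
boundary of the choroid, whose interface with the sclera is low-contrast,
speckled and interrupted by vessel shadows.  The two boundaries are found
by different means, reflecting how different the two problems are:

1. **BM (morphology).**  BM is the brightest homogeneous structure in the
   scan, so a fixed binarization threshold plus shape-preserving cleanup
   suffices: binarize at t_b (default 190, foreground = intensity >= t_b,
   saturated pixels included), clean with a 3x3 morphological opening and
   a component-level background test (a component survives only if its
   mean intensity exceeds the mean of the local background criterion
   R(x) = (erosion(x) + dilation(x))/2 over the component), apply one 3x3
   erosion to slim the band, keep the dominant contiguous row band of the
   per-row histogram (rows with at least 10% of the peak count), thin the
   band to a one-pixel skeleton, collapse each column to its median
   skeleton row, and interpolate a natural cubic spline through every
   10th knot (endpoints kept, linear extrapolation outside).

2. **Choroid (learned voting).**  A small CIFAR-10-style convolutional
   network classifies 32x32 patches as on-line (containing the lower
   choroid boundary) or off-line.  At inference the scan is masked to
   black above the segmented BM, windows are enumerated at stride 5,
   windows whose black share exceeds 1/3 are discarded, and every
   positively classified window adds one vote to each pixel it covers in
   a counter matrix.  The per-column argmax of the counter matrix (ties
   to the smallest row, zero-vote columns omitted) gives candidate
   boundary points; a least-squares cubic polynomial through them,
   clamped to at least one pixel below BM, is the boundary.

3. **Thickness map.**  Per column, thickness is choroid(c) - bm(c) in
   pixels (the curves are single-valued functions of column, so vertical
   distance is the surface distance).  Stacking 25 scans gives a
   25 x 760 en-face matrix; microns follow from 200 um per 76 axial px,
   200 um per 25 lateral px and the 240 um scan spacing, so the nominal
   matrix spans (25-1) x 240 = 5760 um by 760 x 200/25 = 6080 um.

## Thinning and the connectivity number

The thinning deletion test is based on counting the foreground arcs
around a pixel with the cyclic sum
C_n = sum_{k in {1,3,5,7}} N_k - N_k N_{k+1} N_{k+2}
(neighbours numbered counter-clockwise from the right-hand pixel,
indices wrapping).  `connectivity_number` implements exactly this form.
Taken literally it only sees arcs that touch a 4-neighbour, so a pixel
whose removal would detach a diagonal-only branch can still score 1.
`thin` therefore evaluates the same sum on the *complemented*
neighbourhood (the classical 8-connectivity form), which counts every
arc, and deletes a pixel only when that count is 1 and its
foreground-neighbour count lies in [2, 6] (isolated pixels and line
endpoints are protected).  Peeling alternates north-border and
south-border subiterations with sequential in-pass deletion.  Peeling
only vertically is a deliberate specialization to the near-horizontal
BM band: it collapses the band onto its centreline without ever
shortening it horizontally, and it preserves the number of connected
components (verified exhaustively in the tests).  The trade-off is that
the routine is not a general-purpose skeletonizer - tall vertical
structures erode from their ends - which is irrelevant for retinal
layer bands.

## The patch classifier

Architecture: three blocks of 5x5 stride-1 'same' convolution -> ReLU ->
3x3 stride-2 ceil-mode max pooling (channel widths 32, 32, 64; spatial
sizes 32 -> 16 -> 8 -> 4), a 64-wide fully connected ReLU layer and a
2-way softmax head.  Grayscale patches are replicated into three input
channels - the 3073-byte record format (1 label byte + three 1024-byte
colour planes, row-major) is a colour format, and replication preserves
it literally - and scaled to [-0.5, 0.5].

The objective is the mean negative log-likelihood of the true labels
under the softmax (one-hot targets) plus weight decay
(lambda/2)||W||^2 with lambda = 5e-4 over weight tensors only.
Optimization is mini-batch SGD, batch 50, momentum 0.9
(v <- 0.9 v - eta (grad + lambda W); theta <- theta + v), learning rate
1e-3 stepped to 1e-4 at epoch 21 in the 40-epoch full profile.  The
**reduced profile** (epochs 5, at most 10,000 balanced patches) is the
desk-scale default used by the tests, the worked example and the
acceptance script; it was chosen as the smallest budget at which the
phantom study is comfortably learnable, and all of its settings are
ordinary config values.  Everything is implemented in numpy (im2col
convolutions in NHWC layout, explicit backprop); the analytic gradient
is checked against central finite differences in the test suite, and
training is bit-reproducible for a fixed seed.

Initialization is He-normal for convolutional and hidden weights,
N(0, 0.01) for the softmax head, zero biases, all drawn from one seeded
generator.  Prediction maps a patch to argmax of the class
probabilities with ties resolved to the off-line class.

## Training data sampling

Training scans are masked above the *ground-truth* BM (at inference the
automatically segmented BM takes that role), windows enumerated at
stride 5 top-to-bottom/left-to-right, overly black windows discarded
(strictly more than 1/3 zeros, i.e. 342 of 1024), and a window is
labeled 1 when the rounded truth curve passes through it.  Off-line
windows vastly outnumber on-line ones, so the majority class is
subsampled (seeded, without replacement) to the minority count; a
`max_patches` cap subsamples both classes equally.  The black-pixel test
uses intensity exactly 0 because the mask writes literal zeros.  No
augmentation is applied; the sampler exposes the patch stream, so
augmentation can be layered on top if ever needed.

## The phantom generator

Clinical OCT volumes with expert annotations are not publicly
available, so the package ships a seeded phantom generator whose layer
stack reproduces the features that drive both pipeline stages: dark
vitreous (~20), mildly textured retina (~100), a bright BM band exactly
3 px thick (~220, the only structure above the 190 threshold), a
choroid (~90) carrying mean-one gamma multiplicative speckle (shape 4
easy, 2.5 hard) and dark elliptical vessel cross-sections (~50), and a
smooth sclera (110 easy, 96 hard - the hard setting makes the
choroid-sclera step nearly invisible, which is the clinically hard
case).  Additive Gaussian noise (sigma 2 easy, 5 hard) is applied last.
Boundaries are a per-volume quadratic plus one low-frequency sinusoid
with amplitude `waviness_amplitude` (default 8 px), and a bounded
random-walk drift (<= 2 px per scan) across the 25 scans of a volume;
choroid thickness is 90-115 px.  Ground truth is exact by construction.
All randomness flows from one seed; identical parameters give
bit-identical volumes.

What the phantom does *not* emulate: physically realistic OCT speckle
statistics (correlated, depth-dependent), pathology (drusen, edema,
RPE detachment), motion artefacts, vendor-specific intensity curves,
or boundaries that leave the field of view.  Passing the phantom study
therefore demonstrates that the pipeline's machinery is correct and
self-consistent, not that its accuracy transfers to clinical scans.

## Numerical and convention choices

* Coordinates: row 0 at the top, column 0 at the left, 0-based; curves
  are real-valued rows indexed by integer column.
* Binarization includes intensity 255 in the foreground.
* Skeleton-column ties: the knot is the median of the column's skeleton
  rows (midpoint average for even counts).
* Positive signed boundary error means the prediction sits deeper
  (larger row) than the truth.
* The thickness-vector error err1 is the rooted Euclidean norm of the
  difference divided by h*w; err2 is |mean difference| / h with h the
  scan height.  The Dice region per curve pair is
  {(r, c): bm(c) < r <= choroid(c)} with rounded curves; two empty
  regions score 1.
* The counter matrix uses increment-by-one voting; per-column argmax
  would be degenerate on a set-to-one matrix.
* The black-fraction discard rule is applied at inference exactly as in
  training, and discarded windows cast no vote.
* Curve fits: the BM spline is a natural cubic through subsampled
  knots; the choroid fit is an ordinary degree-3 least squares on a
  centred/scaled abscissa (conditioning only; same polynomial family).
* File writes are atomic (temp file + rename); boundary CSVs store 9
  significant digits, which round-trips well below 1e-6.

## Problem sizes used by the shipped study

The scaled-down study behind the tests and `scripts/acceptance.py`
trains on 3 phantom subjects (75 scans, balanced and capped at 10,000
patches) with the reduced profile and evaluates on one held-out
25-scan volume at full 456 x 760 geometry.  Typical results (seed 1):
BM MAE ~0.2 px, choroid MAE ~2.5 px, inter-boundary Dice ~0.99,
holdout patch accuracy ~0.97.  These sizes are the package's default
worked example; the full 40-epoch profile and arbitrarily many
subjects are plain configuration changes.

## Known limitations

* The thinning routine is specialized to near-horizontal bands (above).
* The axial scale 200/76 um/px applied to a 456-row scan implies an
  unusual physical depth; the constants are used as given, and all
  unit conversions are exact elementwise scalings, so correcting the
  scale is a one-line config change.
* BM must be present across the full scan width; scans where the band
  leaves the field of view raise a segmentation error rather than
  returning a partial curve.
* The classifier is trained per-study; no pretrained weights ship with
  the package.
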