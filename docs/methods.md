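# Methods

## Problem and pipeline

Glaucomatous damage thins the neuroretinal rim — the annulus between the
optic-disc margin and the cup. Screening measures therefore compare cup
and disc geometry: the vertical cup-to-disc ratio (CDR), the cup/disc and
rim/disc area ratios (CDAR, RDAR), and the rim thickness around the full
circle. `fundusseg` estimates these from a fundus photograph in three
stages: (1) locate the optic disc and crop a square ROI, (2) segment disc
and cup inside the ROI with a convolutional network, (3) compute the
measures and, when ground truth is available, their errors.

Every stage has an oracle mode (ground truth substituted for the stage's
output), so each downstream stage is testable in isolation — the pipeline
is a pure composition of module functions and running stages individually
reproduces `run_pipeline` bit for bit.

## ROI stage

A detector is any callable `image -> [RoiCandidate]` where a candidate
carries a binary mask, its tight bounding box `(x_tl, y_tl, x_br, y_br)`
(0-based, x = column), and a probability. Selection takes the maximum
probability, breaking ties by larger mask area and then list order. The
crop is a square of side `round(factor × longest bbox side)` centred on
the bbox centre; `factor` defaults to 2.0 (the best of
{1.25, 1.5, 1.75, 2.0} in the experiments the design follows), and
out-of-frame regions are zero-filled, consistent with the black-background
convention used when remapping segmentations. Side lengths are coordinate
differences (`x_br − x_tl`); whether the crop is centred on the bbox or
anchored elsewhere is not fixed by the source description — centring is
this package's reading.

Training or re-implementing an instance-segmentation detector (Mask
R-CNN) is explicitly out of scope; the bundled intensity detector
(Gaussian smoothing, Otsu threshold, connected components scored by
normalised mean brightness) stands in for synthetic-style images, and an
adapter slot accepts an external detector satisfying the same contract.

## Segmentation network

Input is a 512×512×3 ROI (or 128×128×3 for the reduced preset); output is
512×512×2 class scores.

**Encoder (DNFE).** A DenseNet-121-style encoder — 7×7/2 stem convolution
(2·growth channels), BN-ReLU, 3×3/2 max-pool, then three dense blocks of
6/12/24 layers with growth rate 32, each layer a BN-ReLU-1×1(4·growth)
bottleneck followed by BN-ReLU-3×3(growth). Taps: scales 1–2 are taken
after the transition layer's 2× channel compression but *before* pooling
(128 and 256 channels at 128² and 64²); scale 3 is the raw third-block
output (1024 channels at 32²). This tap placement is the only one
consistent with the published combined totals (512, 640, 1408) given a
384-channel pooling extractor.

**APFE.** Per tap, three branches with average-pooling windows (2, 4, 8):
pool, project to 128 channels by 1×1 convolution (BN + ReLU), bilinearly
upsample back, concatenate → 384 channels at the tap's resolution. The
window sizes and the even 3×128 channel split are not specified by the
source description; these defaults are the package's choice and are
configurable. Each tap is paired with its own scale's APFE output
(self-pairing); the alternative cross-scale pairing is not implemented
because the published shapes cannot distinguish the two.

**Decoders and ensemble.** Each concatenated tensor feeds one transposed
convolution with stride equal to the scale's upsample factor (4, 8, 16)
and kernel 2×stride (avoiding checkerboard gaps), producing a full-
resolution 2-channel map. The final 1×1 convolution over the three
stacked head outputs (6 channels) combines them — an embedded ensemble.
Only this combined output is supervised; per-head deep supervision is a
possible alternative reading not taken here.

**Training.** Per-pixel softmax cross-entropy, Adam (lr 1e-4, β₁ 0.9,
β₂ 0.999, ε 1e-7, decay 0), batch size 20 (4 for the reduced preset), up
to 100 epochs, 80/20 train/validation split, and the checkpoint with
minimum validation loss restored at the end. Images are z-scored per
channel with their own moments before entering the network. Training is
from scratch (no ImageNet transfer). Augmentation for the segmentation
stage is a vertical flip × rotations (−10°, −5°, 0°, 5°, 10°) → 10
variants per ROI; the wider ROI-stage set (±20° by 10°) is kept as a
separate configuration entry but unused since the detector network is out
of scope. Two independent binary networks (disc, cup) are used; a single
3-class variant is a non-goal.

**Numerical engine.** The environment provides no deep-learning
framework, so `fundusseg.nn` implements the needed operations in numpy:
im2col-based convolution, transposed convolution as the convolution
adjoint, batch normalisation with running statistics, non-overlapping
average pooling, 3×3/2 max pooling, integer-factor bilinear upsampling
(half-pixel centres), reverse-mode autodiff on a recorded tape, and Adam.
Gradients of every op are verified against central finite differences in
the test suite. All computation is float32; training is deterministic
given the seed.

## Key measures

- Centroid: arithmetic mean of foreground (column, row) coordinates.
- Vertical diameter: `max_row − min_row + 1` of the mask — the natural
  pixel reading, robust to non-convexity.
- Radius profile: boundary pixels are foreground pixels with a background
  4-neighbour; each is binned to its nearest degree (bin `[m−0.5°, m+0.5°)`,
  0° horizontal right, counter-clockwise) and the farthest pixel per bin
  gives the radius; empty bins are filled by circular linear interpolation.
  Cup radii are measured from the *disc* centroid so that the rim radius
  is a meaningful per-angle difference.
- Rim profile: disc radius minus cup radius per angle; negative values
  (estimated cup boundary outside the disc) are clamped to 0 and flagged
  per angle rather than propagated as negative thickness.
- Ratio errors: `|r_GT − r_est| / r_GT` per angle; angles with zero GT
  radius are excluded from both numerator and denominator of the average.
  The circle average uses 360 samples, m = 0…359 — one per degree with no
  double-counted endpoint.
- Scalar errors: absolute GT-vs-estimate differences of CDR, CDAR, RDAR.
  When the cup is contained in the disc on both sides, CDAR + RDAR = 1
  forces CDARE = RDARE.

## Evaluation

JI, DC, sensitivity, specificity, accuracy from pixel confusion counts;
zero-denominator metrics are reported as undefined (None) rather than
coerced. Identities `DC = 2·JI/(1+JI)` and `JI ≤ DC` hold by construction.
Multi-group summaries weight group means by test-image counts. Error
histograms use half-open bins `[k·w, (k+1)·w)` with w = 0.01 by default,
so a value on a boundary lands in the upper bin and "below 0.03" is the
first three bins exactly.

## Synthetic data

The generator emulates the appearance that drives the method: a dark
reddish retina background, a bright elliptical disc containing a brighter
elliptical cup (intensity layering background < rim < cup), dark
Bézier-stroke vessels radiating from the disc, and additive Gaussian
noise. Masks are exact pixel-centre rasterizations of the generating
ellipses and are never altered by vessels or noise — geometric truth,
matching how human annotation ignores vessels crossing the disc. The cup
is the disc scaled by `cup_to_disc_factor ∈ (0, 1]` with an offset clamped
(largest admissible fraction, found by bisection) so the cup stays inside
the disc.

Default sampling ranges (image 256², disc semi-axes 40–70 px, axis ratio
0.85–1, cup factor 0.3–0.8, rotation ±20°, centre jitter ±20 px, cup
offset σ 3 px, noise σ 8, 4 vessels) are chosen to resemble typical
fundus ROI geometry and CDR ranges seen in screening populations. The
"easy" desk-scale conditions used in tests (128², semi-axes 22–38, noise
σ 5, 2 vessels) keep a short CPU training run meaningful.

What the generator does *not* emulate: photometric vignetting, camera
blur and compression, peripapillary atrophy, pathology (hemorrhage,
drusen), true vessel branching, and the genuinely ambiguous cup boundary
of real photographs. Passing tests therefore demonstrate that the
pipeline, network and measures are implemented correctly and can learn
and recover geometry under controlled conditions — not that real-image
accuracy figures are reproduced; those require the original corpora and
GPU-scale training.

## Problem sizes and defaults in the test suite

Desk-scale runs use the reduced network (growth 8, blocks 2/2/4, APFE 24
channels, input 128, batch 4): 200 training images for the learning
check (held-out disc JI > 0.8 after 10 epochs), 40 images for
loss-decrease checks, 50 images for parameter recovery. The full-width
network is built and run forward once to verify the published stage
shapes; it is never trained in the suite.

## Known limitations

- The intensity detector is designed for synthetic-style images; real
  fundus photographs need an external detector through the adapter.
- Bilinear upsampling and float32 arithmetic make network outputs
  reproducible per platform/BLAS, not bit-identical across platforms.
- The radius profile assumes a roughly star-convex mask around the
  centroid; for pathological shapes the farthest-pixel-per-bin rule picks
  the outermost boundary crossing.
- Checkpoints store raw weight arrays with a JSON config sidecar; they
  are not portable to other frameworks.
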