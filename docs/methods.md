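# Methods

## The image model

A corneal reflection (CR) in a high-quality eye image is well described by
an isotropic 2-D Gaussian light distribution that heavily oversaturates
the camera.  `crloc.synthcr` renders

    G(x, y) = A · exp(−((x − x_c)² + (y − y_c)²) / (2 σ_w²))

in *saturation units*, where intensity 1.0 corresponds to the 8-bit
ceiling (255 levels).  The amplitude `A > 1` controls how deeply the
Gaussian saturates; the width is not free but derived from the requested
saturated-disk radius `r`,

    σ_w = r / sqrt(−2 · log(1/A)) = r / sqrt(2 · log A),

so that the pre-clip intensity at distance `r` from the center is exactly
1 for every amplitude.  A useful closed form follows: the pre-clip value
at distance `d` is `A^(1 − (d/r)²)`.  Hence the saturated disk (d ≤ r) is
invariant under `A`, while the tails *shallow* as `A` grows — at `d = 2r`
the value is `A⁻³`.  (A naive "image is monotone in A" intuition is
therefore wrong outside the disk; the test suite pins down the correct
invariant.)

The background emulates the pupil–iris border: two sections of different
luminance (image levels) split by a straight edge smoothed with a
raised-cosine profile over a 4-px band.  With signed perpendicular
distance `d` from the edge, the dark-side blend weight is
`b(d) = ½(1 + cos(π(d + 2)/4))` for `d ∈ [−2, 2]`, clamped outside, with
the dark side at `d ≤ −2`; a pixel exactly on the edge renders at the
mid-level.  The CR is composed with `max(CR·255, background)`, i.i.d.
Gaussian pixel noise of SD `σ_n` levels is added, and the image is
clipped to [0, 255], rounded to integer levels and scaled to [0, 1] — an
8-bit camera image on the k/255 lattice.

Coordinates are 0-based with `x` the column and `y` the row index; pixel
centers sit at integer coordinates and the Gaussian is point-sampled at
pixel centers (no area integration — the simplest reading of the model,
and the one under which all closed-form checks hold exactly).  The
"center" of the 180-px patch is taken as 90.0 so that the stage-2
sampling range [89.25, 90.75] spans exactly 1.5 px around it.

### Training-stage sampling distributions

Stage 1 (broad): `r ~ U[1, 30]` px; center coordinates `~ U[r, 180−r]`;
`A ~ U[2, 20000]` (linear scale); a point on the background edge drawn
per-axis from `Normal(CR center, 1.5 r)`; edge orientation `~ U[0, 2π)`;
dark level `1 + Exponential(scale 10)` levels; light level
`I ~ U[32, 153]`; `σ_n ~ U[0, 30]`.  Stage 2 is identical except both
center coordinates are `~ U[89.25, 90.75]`.  The rare exponential draws
(≈4%) that would make the dark section at least as bright as the light
section are rejected and redrawn, preserving the dark < light ordering
the two-section construction assumes.

Evaluation sweeps use a *vertical* edge placed `E` CR radii from the CR
center (moving with it as the center steps), lighter section on the left;
`E = none` ("no gray") is a uniform dark background.  The sweep dark
level is fixed at 10 levels (configurable); the default grids are
`r ∈ {2,…,18}`, `A ∈ {10, 50, 200, 1000, 10000}`, `σ_n ∈ {0,…,18}`,
`E ∈ {none, −1.5,…,1.5}`, `I ∈ {38,…,153}` — 36,000 conditions — with the
horizontal center stepped through 100 shifts of 0.01 px per condition and
a fresh noise realization per image, seeded by (base seed, condition,
step) for reproducibility with independent noise.

## Localizers

**Threshold centroid.**  Binarize strictly above a threshold, fill
enclosed holes (4-connectivity), extract bright blobs (8-connectivity),
optionally filter by area bounds and circularity `4πA/P² ≥ 0.6`, select
the largest qualifying blob, and return the unweighted centroid of its
pixels.  The default sweep threshold is **0.7** on the [0, 1] scale:
above the maximum light-background level of the grids (153/255 = 0.6) and
below saturation, so the binarized blob is the CR everywhere on the grid.
(A half-saturation threshold of 0.5 would swallow the light background
section whenever `I > 127.5` and the method would fail its own headline
robustness result; in practice the threshold is a per-recording manual
setting, and it is configurable per run here.)

**Intensity centroid.**  The intensity-weighted center of mass of all
pixels.  It is exact for a symmetric source on a black background and is
therefore used to measure the *best achievable error*: render the CR on a
completely black background, quantize to 8 bits, and record the centroid
error over 100 sub-pixel shifts — the localization floor imposed by
pixelation and quantization alone.  On any non-black or asymmetric frame
the whole-image centroid is badly biased, which is why it is not a
default sweep participant.

**Radial symmetry.**  For every 2×2 pixel cell, the two diagonal
intensity derivatives are computed on the half-pixel midpoint lattice
(midpoints at +0.5 offsets), smoothed with a 3×3 boxcar, and converted to
a gradient vector.  Each midpoint `p_k` defines a line along its gradient
direction; for a radially symmetric spot all lines pass through the
center.  The center is the minimizer of `Σ_k w_k · dist⊥(q, line_k)²`
with weights `w_k = |∇I|²_k / d_k`, where `d_k` is the distance from the
midpoint to the gradient-magnitude-weighted centroid.  Lines are
parameterized by unit direction vectors, so the minimizer is the solution
of a 2×2 linear system with no slope singularities; a singular system
(e.g. all gradients parallel) raises an error.  Midpoint-to-centroid
distances are floored at 1e−9 px to avoid a division by zero for a
midpoint coinciding with the centroid.  The closed-form solve is verified
against a brute-force grid search of the same objective (0.001-px final
grid) on random images.

## The CNN

Architecture (configurable via `ModelConfig`; defaults): 180×180×1 input;
seven 3×3 convolutions with filter counts 64, 64, 128, 128, 256, 256,
512, ReLU activations, 2×2 max pooling after each of the first six
(a "block" = conv + pool); flatten; dense 256 + ReLU; dense 2 outputting
the CR center in absolute patch pixels (so the MSE training loss is in
px² on the same scale as the reported errors).  The final bias is
initialized to the patch center, making the untrained network predict the
geometrically sensible point.  These internals (kernel sizes, pooling,
activations, dense width) are standard VGG-style choices; only the layer
count and the 64→512 filter progression are fixed by the design.

Training: Adam, MSE, batch size 4, at most 700 epochs with early stopping
(patience 30 epochs, restore-best-weights, the pre-training weights
included as the initial "best").  Every training image is freshly
generated, so the model never sees an image twice; an *epoch* is defined
as 512 new images (configurable).  Validation uses a fixed 300-image set
drawn from the same stage's distribution; validation error is the mean
Euclidean distance in px, logged per epoch alongside the MSE loss.
Stage 1 uses learning rate 1e−4 on the broad distribution.  Stage 2
initializes from the stage-1 weights, freezes the first two convolutional
blocks, and fine-tunes the rest at 1e−6 on the near-centered
distribution.  Training is deterministic given the seed (all draws flow
from one seeded generator; the float32 NumPy engine has no other
randomness), and weights serialize to a single portable `.npz` archive.

The network runs on a compact NumPy layer engine (`crloc._nn`) with
explicit backpropagation — sufficient for CPU-scale experiments, not for
GPU-scale ones.  **Problem sizes used by the test suite** (the package's
own desk-scale choices): the memorization harness trains the full-width
architecture on 10 fixed images for up to 500 Adam steps at its own
learning rate of 1e−3 (the harness probes trainability of the
architecture, not the staged schedule, and 1e−4 cannot traverse the
initial px²-scale loss landscape in 500 steps); staged-training behavior
(frozen blocks, no-regression guarantee) is exercised with a
reduced-width seven-conv configuration (8…64 filters) and short epochs.
Reaching the full-scale two-stage operating point (validation errors of
roughly 0.23 px after stage 1 and 0.09 px after stage 2) requires tens of
thousands of training images and is an overnight-scale CPU run with this
engine; the test suite verifies the architecture and procedure, not those
endpoint numbers.  Consequently the shared CNN fixture used in the
pipeline tests is a reduced-width model briefly trained on near-centered
patches with the 48-px inference mask applied; it localizes fixture CRs
to well under a pixel but is far from the full-scale model's sub-0.1-px
regime.

## Eye-video pipeline

Frames are processed strictly independently (no temporal state; tested by
permutation invariance).  Coarse stage: within an optional ROI, the pupil
is the largest dark blob below the pupil threshold and the CR the largest
bright blob above the CR threshold, after hole filling and area /
circularity screening; centers are binary-blob centroids.  Refinement
stage: a 180×180 cutout centered on the *rounded* coarse CR center
(integer cropping keeps patch pixels aligned with frame pixels), masked
to black outside a 48-px circle about the patch center, is fed to radial
symmetry and/or the CNN; patch estimates map back to frame coordinates by
adding the cutout origin.  Cutouts that run over the frame border are
zero-padded and flagged so downstream analysis can exclude them.

The half-resolution variant downsamples frames by 2×2 block averaging
(a full-resolution coordinate `x` maps to `(x − 0.5)/2`), halves the mask
radius to 24 px, and scales ROI and area criteria accordingly.

The synthetic eye-frame generator emulates the features the pipeline
keys on: a uniform iris-level background, a darker pupil ellipse, one
saturated CR (same compose/noise/quantization chain as the patches), and
optional pixel noise.  It does **not** emulate eyelids, eyelashes,
glasses reflections, corneal texture, off-axis illumination gradients or
motion blur — passing fixture tests therefore demonstrates correct
plumbing and method behavior on idealized frames, not performance on real
recordings.  One real-data effect the fixtures *do* reproduce: when the
pupil edge crosses the masked cutout, the radial-symmetry estimate is
visibly biased by the non-uniform background (fixture errors of a few
px), while the CNN and threshold stages are not — the masked cutout keeps
that edge inside the CNN's input just as in real processing.

## Calibration and data-quality metrics

Gaze is `pupil − CR` per sample (invalid samples propagate), calibrated
per axis with `p_gaze = a + bx + cy + dx² + ey² + fxy` fitted by least
squares on one median P-CR point per calibration fixation (3×3 grid at
h ∈ {−7, 0, 7}°, v ∈ {−5, 0, 5}°; the median is the per-fixation
reduction because it is robust to blinks and saccade tails).  Accuracy is
evaluated on the 5×3 grid (h ∈ {−7, −3.5, 0, 3.5, 7}°): per fixation the
Euclidean distance between the per-axis median gaze and the target,
averaged first over repetitions of each target, then over targets.

Precision metrics use moving windows of `floor(0.2 s × rate)` samples
advancing one sample at a time, reporting the median across windows:
RMS-S2S is the within-window RMS of Euclidean sample-to-sample
displacements; STD is `sqrt(var(x) + var(y))` with population variances.
These are the combined 2-D forms (per-axis output is a configuration
choice away); for i.i.d. noise of SD σ per axis they satisfy
RMS-S2S ≈ 2σ and STD ≈ σ√2, a consistency relation the tests verify by
Monte Carlo.

## Known limitations

* The NumPy engine makes full-scale CNN training an overnight CPU job;
  the packaged tests operate at reduced width / step counts as described
  above.
* Radial-symmetry weighting follows the original particle-tracking
  formulation (boxcar-smoothed diagonal derivatives); other ports may
  smooth slightly differently, shifting absolute error levels by small
  amounts in heavy noise.
* MP4 decoding requires an imageio ffmpeg backend; directories of PNG
  frames (or in-memory arrays) are the dependency-free input path.
* The simulator renders a single CR with an isotropic Gaussian PSF;
  multiple CRs, astigmatic PSFs and photo-realistic eye rendering are out
  of scope.
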