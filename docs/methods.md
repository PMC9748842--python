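# Methods

## Problem setting and model

The package registers a moving image (histology-like, bright-field) onto a
fixed image (MR-like, dark-field) in 2-D.  The registration is resolved from
predicted homologous point pairs rather than from directly regressed
transform parameters, which makes the pipeline transform-agnostic (any
transform fittable from two point clouds could consume the pairs; a
thin-plate spline is what ships) and lets it operate on unmasked images.

**Coordinate convention.**  All points are `(y, x)` = (row, column),
0-based, continuous, with pixel `i` spanning `[i, i+1)` so the center of
pixel `i` is `i + 0.5`.  Every resampling call converts to numpy's
index-center convention by subtracting 0.5; keypoint detection converts back
by adding 0.5.  Patch centers form the meshgrid `p/2 + p·k` (range
`[p/2, size − p/2]`, spacing `p`), which is the same convention.

**Preprocessing.**  Images are min–max scaled to [0, 1] (RGB first collapsed
with BT.601 luma weights), the organ's bounding box is found by Otsu
thresholding with modality-dependent polarity (tissue is dark on a light
field in histology, bright on a dark field in MR) and removal of connected
components below 0.1% of image area, and the box is zoomed so that its
longer axis spans the output minus a 50-px margin on either side, aspect
preserved.  The zoom is a similarity transform; point annotations ride
through it exactly.  A user-supplied bounding box overrides the automatic
one.

**Landmark selection.**  Difference-of-Gaussians scale-space extrema
(26-neighborhood), with Lowe-style defaults: 3 scales per octave, σ₀ = 1.6,
an initial 2× upsampled octave (input blur assumed 0.5 px), octaves until
the smaller dimension drops below 16 px.  One step of quadratic sub-pixel
refinement is on by default, and contrast is the interpolated |D(x̂)|
(a `refine=False` flag gives the raw lattice value).  Candidates below
contrast 0.04 are dropped; the remainder are scored with Tr(H)²/Det(H) of
the 2×2 spatial Hessian — monotone in the eigenvalue ratio for Det > 0,
with Det ≤ 0 (saddles) sent to +∞ — and the top ⌈0.19·n⌉ by score are
labeled edges (ties break by higher contrast, then scan order).  Greedy
minimum-distance thinning visits all edge points in descending contrast
order, then all interior points in descending contrast order, keeping a
point iff it is at least `min_dist` from everything already kept; an
interior point therefore always loses a conflict with an edge point.  If
more than `max_points` survive, lowest-contrast interior points are dropped
first.  `min_dist` defaults to 30 px at 512×512 (the spacing is a density
knob, not a fitted constant).

**Network.**  Patch CNN: two 2×2/stride-2 convolutions with 64 channels and
a final (p/4)×(p/4) convolution to d channels, GELU activations, plus a
learned position embedding per patch (unshared between branches, like all
weights).  Encoder: pre-norm locality-preserving blocks — multi-head
self-attention (4 heads, 1/√d_h logit scaling) with residual, then a
convolutional feed-forward (1×1 expand to 4d → GELU → 3×3 depthwise → GELU
→ 1×1 project) applied on the √N×√N spatial reshape of the tokens, with
residual.  Six blocks of d = 128 at the default configuration.  The
similarity between gathered landmark encodings and all fixed-image patch
encodings is a plain dot product with a row softmax — deliberately *no*
1/√d scaling there (a temperature knob exists, default 1).  The soft-argmax
multiplies each row by the patch-center meshgrid; adding the landmark's
within-patch offset `(X mod p) − ⌊p/2⌋` yields the final prediction, and
rows belonging to padding landmarks are masked to (0, 0).

The patch size is exposed (`patch_size`, default 16 → N = 1024 patches at
512²) rather than fixed: no single value reproduces the reference
parameter count exactly, so `count_parameters(config)` is provided for
anyone wanting to search configurations.

**Initialization.**  He-style init for general weights, N(0, 0.02) position
embeddings, and near-zero (σ = 1e-3) residual output projections so each
encoder block starts close to the identity.  Without that last choice the
unscaled similarity softmax saturates at initialization (row entropies
≈ 1e-7) and gradients vanish; with it the logit spread starts near 1 and
training is stable.  This is the one place where the absence of logit
scaling has to be compensated in the init rather than the architecture.

**Thin-plate spline.**  Kernel U(r) = r² log r with U(0) = 0, coordinates in
pixels by default (a `coord_scale` flag fits in rescaled units, which
conditions the system differently), bordered linear system with
regularization λ added to the kernel diagonal.  λ = 0 interpolates exactly (duplicate or collinear sources are
detected and named in the error); λ > 0 trades residual for smoothness and
monotonically lowers bending energy wᵀKw.  Image warping is backward: the
spline fitted in the fixed→moving direction maps each output pixel center
into the moving frame for bilinear sampling, 0-filled outside.  When a
*forward* spline must drive image resampling (augmentation, phantom
rendering), its numerical inverse is found per pixel by fixed-point
iteration `m ← m − (f(m) − q)` (8 iterations; sub-1e-3 px for the smooth,
small-displacement fields used here).

**Training.**  Masked MAE over valid points (mean of |Δy| and |Δx|), Adam
(default lr 1e-4, batch 4 by gradient accumulation — optimizer and batch
size are not externally specified, these are ordinary defaults), optional
cosine learning-rate decay, 128 epochs by default.  Augmentation: a 4×4
control grid displaced per-axis uniformly within ±16 px defines a random
TPS applied to both sides (points mapped forward, images through the
inverse); the fixed side additionally rotates by U(−20°, +20°) about the
image center.  Mixing schema: each example is mono-modal with probability
0.5 (per-example Bernoulli; the expectation matches a stratified half-split
and stays seeded), in which case one slide and one modality are chosen and
both branches receive differently-augmented copies, with the patch-encoder
branch switched so histology weights never see MR pixels and vice versa.  A
probe test asserts the gradient isolation.  Best-validation weights are
checkpointed alongside the final ones.

**Evaluation.**  Control point deviation = mean Euclidean distance between
ground-truth fixed-frame points and ground-truth moving-frame points mapped
through the *resolved* transform — the transform is always fitted on the
pipeline's own landmark/prediction pairs, never on the ground truth being
scored; the API keeps the two point-set roles in separate arguments.  Dice =
2|A∩B|/(|A|+|B|), with both-empty defined as 1.0 (a NaN mode exists).
Deviation is reported in the preprocessed frame; the stored zoom transforms
allow conversion to original pixels.

## The phantom generator

Each phantom emulates one whole-mount-slide/MR-slice pair: an organ-scale
blob (circle with low-order Fourier radius perturbation, radius 24–32% of
the image), 2–5 internal structures (a central lumen plus lobe-like
sub-regions, same curve family), and a shared mid-scale "parenchyma" noise
field.  Each contour also carries an angular morphology profile (capsule
thickness / gland density variation along the curve) that belongs to the
*geometry*, because it is a tissue property: the histology render shows it
as bead-like staining variation (which also gives the DoG detector
realistic features to find), the MR render as brightness/thickness
modulation of the capsule rim.  Without that shared profile the tangential
position of a contour landmark would be unrecoverable from the MR side —
whereas the clinical ground truth the phantom stands in for consists of
human-placed homologous points, localizable in both modalities by
construction.  The MR render is dark-field, blurred, with coarse noise and
an *inverted* intensity mapping of the same parenchyma field.  The fixed frame is rendered
from geometry passed through a random TPS whose control displacements are
rescaled so the mean displacement over the ground-truth points equals
`deformation_px` exactly — so "a magnitude-12 phantom" has a mean
ground-truth displacement of 12 px by construction.  Ground-truth pairs
(half on the organ boundary, half on structure contours) are related by the
forward spline exactly; rendering uses the approximate inverse, which is
irrelevant to the point-pair invariant.  Degradations (`tear`: crack-polygon
removal, without edge displacement; `fold`: mirrored overlaid strip;
`partial`: guillotine crop to a target mask fraction) invalidate the
ground-truth points they destroy.

What the phantoms do *not* emulate: real stain variability, scanner
artifacts, partial-volume effects, histology texture that has no MR
counterpart at all, and non-smooth deformations (true tears between the
modalities).  Passing the synthetic recovery study therefore shows the
pipeline's machinery is sound and learnable, not that clinical accuracy
transfers.

## The scaled-down recovery study

`homopoint.experiments.run_synthetic_recovery_study` sizes the problem for
one CPU: 128×128 phantoms, patch 8, d = 32, two blocks, 4 heads, L = 32;
200 training phantoms, 6 validation, 20 held-out test phantoms at 12 px
mean displacement; 30 epochs × 27 steps × batch 4 with lr 2e-3 under
cosine decay; augmentation scaled to the frame (TPS cap 4 px, rotations
±5°); landmark spacing 10 px; TPS λ = 50 when fitting the (noisy)
predicted pairs.  Reported: pipeline vs identity mean control point
deviation, percentage reduction, registered vs unregistered Dice and the
per-phantom improvement count, plus the deviation of a TPS resolved directly
from the ground-truth pairs (near zero — limited only by spline degrees of
freedom).

## Numerical choices and degenerate inputs

* float64 throughout the network; forward passes are deterministic, and
  tests compare at 1e-6–1e-7 where reassociation allows.
* Constant images normalize to all-zeros; a constant image has no foreground
  and raises a named error from the bounding-box finder.
* Landmark sets larger than L raise with advice rather than silently
  truncating at the padding step; the selector itself thins to `max_points`.
* Invalid points are tracked by an explicit boolean mask; the (0, 0)
  sentinel appears only at model I/O boundaries, so a genuine point at
  (0, 0) cannot be confused with padding anywhere else.
* Gathering for invalid landmarks reads patch 0 purely to keep shapes
  static; the output mask guarantees those rows are (0, 0) regardless.
* Both-empty Dice = 1.0 by default (vacuous agreement); NaN available.

## Known limitations

* No GPU path; the autodiff engine is deliberately minimal and CPU-bound,
  so full-scale (512², d=128, six-block) training is slow — the default
  configuration is provided for completeness and inference-scale use.
* Only TPS (and its affine subset) ships as a resolver.
* The landmark detector computes no descriptors; it is a detector only, as
  the pipeline requires.
* 2-D only; volumes are out of scope.
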