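# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `segscale`, and what the desk-scale test setup does and
does not demonstrate.

## Problem setting

Biodegradable metal implants (e.g. magnesium-alloy screws) are imaged in bone
by high-resolution X-ray microtomography. Segmenting the volumes into
background, bone, degradation layer (DL) and residual material (RM) enables
three standard morphometric measures:

* **degradation rate** `DR = ((v_i − v_r) / a_i) / t` in mm/year, where
  `v_i`, `a_i` are the implant's initial volume and surface area, `v_r` the
  residual-material volume from the segmentation, and `t` the implantation
  time in years;
* **bone-implant contact** `BIC = b / a`, the fraction of implant boundary
  voxels in face contact with bone;
* **bone volume fraction** `BV/TV`, bone voxels over total voxels in a region
  of interest (ROI) around the implant.

A 2D U-net predicts per-slice class probabilities; slicing the volume along
several orientations and fusing the per-voxel probabilities ("multi-axes
prediction fusing") recovers most of the benefit of a 3D context at 2D cost.

## Model family and scaling

All networks share one construction rule set:

* encoder blocks: two 3x3 same-padding convolutions, each followed by batch
  normalisation and the Mish activation; 2x2 max-pooling between levels;
* channel doubling: level `l` has `c0 · 2^l` channels;
* decoder: 2x2 stride-2 transposed convolution halving the channels, skip
  concatenation with the matching encoder level, then a two-convolution block;
* head: 1x1 convolution to the class count, softmax.

The scaling grid is the Cartesian product of width `c0 ∈ {32, 64, 96, 112}`,
depth `d ∈ {3, 4, 5, 6}` and input size `{384², 512², 640²}` — 48
configurations. Parameter counts are computed in closed form from the layer
plan (conv3x3: `9·in·out + out`; transposed conv2x2: `4·in·out + out`;
batch-norm: `2·out`); the flagship `(c0=96, d=5)` model has 279,837,700
parameters.

**Receptive field.** The theoretical receptive field is computed by exact
backward interval propagation through the layer plan (conv3x3 widens an
interval by 1 on each side; max-pool maps `[lo, hi]` to `[2lo, 2hi+1]`;
transposed conv to `[lo/2, hi/2]` with floor division), maximised over all
`2^d` output phases. This is validated in the tests against a direct
gradient-support measurement on instantiated networks (batch normalisation
replaced by identity, strictly positive weights, average pooling in place of
max pooling so gradients reach every contributing input pixel). The values
for depths 1–6 are 18, 44, 100, 204, 412 and 828 px.

## Multi-axes prediction fusing

Three naive slicing sets exist for a volume `V(p, r, c)`: `S_rc` fixes `p`
(`S_n(i,j) = V(n,i,j)`), `S_cp` fixes `r`, `S_pr` fixes `c`. Rotating the
volume in-plane by 45° about each principal axis and slicing along the two
non-parallel axes adds six non-redundant planes (slicing along the rotation
axis would only rotate a naive plane in-plane), nine in total.

Rotation plumbing is chosen for exact invertibility bookkeeping:

* the volume is zero-padded to the ceil of the rotated bounding box before
  rotating (a 100² cross-section becomes 142² at 45°), so no content is lost;
* rotation is bilinear about the padded centre (`scipy.ndimage.rotate`,
  `reshape=False`, zero fill, no spline prefilter);
* back-mapping applies the inverse rotation, centre-crops to the original
  shape, renormalises per-voxel probability mass, and carries a validity
  mask built by rotating a volume of ones forward and back and thresholding
  at 0.999 — voxels whose value is contaminated by zero fill are excluded
  from fusion.

**Soft voting** averages the per-plane probability fields, restricted at each
voxel to the planes whose validity mask covers it, then takes the arg-max.
**Majority voting** takes the per-voxel mode of the per-plane arg-max labels;
ties resolve to the lowest class index in both rules, which makes
arg-max-of-soft and majority provably identical on one-hot votes (verified
exhaustively in the tests for three voters and four classes).

## Morphometry conventions

* Surfaces are voxel-count proxies with 6-connectivity; a region voxel is on
  the surface if any face neighbour is outside the region, and volume borders
  count as outside. The implant region is DL ∪ RM.
* The ROI is the set of voxels whose Euclidean distance to the implant
  (computed with a physically scaled distance transform) is positive and at
  most a chosen radius (default 500 µm); the implant itself is excluded.
* `DR` divides by the implantation time so the unit is mm/year. A
  `dr_formula="multiply_t"` switch preserves the alternative multiplicative
  form found in part of the corrosion literature. Negative volume loss (a
  segmentation artefact) is clamped to zero with a warning.

## Phantom design

Real bone-implant tomograms are not publicly deposited, so correctness is
demonstrated on synthetic phantoms with closed-form truth:

* the implant is an axis-aligned circular cylinder: an RM core of radius
  `screw_radius − degradation_shell` inside a DL shell of radius
  `screw_radius` (defaults 250 µm radius, 600 µm length, 100 µm shell);
* the bone is the full Euclidean-distance capsule within `bone_shell`
  (default 150 µm) of the implant — the same distance transform the ROI
  uses, so the phantom's BV/TV denominator matches the quantify ROI by
  construction. The capsule-shell volume has the exact Steiner form
  `S·R + M·R² + (4/3)πR³` with mean-curvature integral `M = πL + π²r` for a
  cylinder;
* trabecular porosity is carved by seeded spherical voids until the bone
  fraction in the capsule reaches the occupancy target (default 0.4), so the
  expected BV/TV equals the occupancy. Void centres keep a margin of
  `void_radius + 2 voxels` from the implant surface, so the first bone layer
  stays intact and the expected BIC is exactly 1; optional planar cracks
  break the contact for negative tests;
* rendering assigns per-class Gaussian intensities (means 0.1 / 0.45 / 0.6 /
  0.9, sigma 0.03) and can add a difference-of-Gaussians overshoot at class
  interfaces to mimic propagation-based phase-contrast edge enhancement.

What the phantom does **not** emulate: realistic trabecular architecture,
screw threads, beam-hardening or ring artefacts, partial-volume blur, or the
intensity overlap between DL and bone that makes the real task hard. It is a
correctness instrument for the geometry/accounting pipeline and a feasible
learning target, not a difficulty benchmark.

## Training protocol

Adam (learning rate 3e-4, betas 0.9/0.999) on plain cross-entropy over
augmented patches sampled from the three naive slicing sets of the training
volumes. Augmentation: random crop of 85–100 % of the slice area with aspect
ratio uniform in [3:4, 4:3], resized to the model input; horizontal flip
(p = 0.5); rotation uniform in ±90°; elastic deformation from a coarse
Gaussian displacement grid (64 px spacing, sigma 10 px, p = 0.3); brightness
±0.1 and contrast 0.9–1.1. The learning rate halves when the validation loss
has not improved for 10,000 iterations and training stops early after
30,000 without improvement; the best-validation checkpoint is returned.
Cross-validation uses a seeded shuffle with round-robin fold assignment
(14 samples → folds of 4/4/3/3).

## Numerical engine

No deep-learning framework is assumed; `segscale.nn` implements the forward
and backward passes in NumPy: im2col convolution via stride tricks, standard
batch-norm backward, Mish, max/average pooling with deterministic arg-max
tie-breaking, einsum-based 2x2 transposed convolution, fused
softmax-cross-entropy, and Adam. Determinism: a single seed fixes
initialisation, batch sampling and augmentation, and repeated runs are
bit-identical.

## Desk-scale problem sizes

The test and acceptance suites run on one CPU core in minutes, which dictates
the package's own choice of demonstration sizes: 64³–200³ phantoms, model
specs down to `(c0=8, d=2)` at 64² input, and hundreds (not millions) of
training iterations. The code paths are identical at full scale — all sizes
are configuration, not code — but the shipped experiments demonstrate
correctness and learnability, not state-of-the-art accuracy on real data.

## Limitations

* 2D slice models with fusion, not a native 3D network; through-plane context
  enters only via multiple orientations.
* Rotated-plane back-mapping uses bilinear interpolation; label boundaries in
  rotated planes carry an interpolation band of roughly one voxel, which is
  why fused agreement checks near boundaries are tolerance-based.
* Surface area by voxel counting is a biased estimator of true area (it does
  not converge to the geometric surface area with refinement); BIC is a ratio
  of such counts, which keeps it usable, and DR uses the analytic or
  reference initial surface rather than a voxel count where available.
* Training at the full published scale (hundreds of millions of parameters,
  10⁶ iterations) is far outside the CPU engine's practical envelope; the
  engine is intended for desk-scale verification and method development.
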