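# Methods

`retinareg` implements a two-stage vascular-landmark detection model and
the feature-based registration pipeline built on it, together with a
synthetic fundus generator that makes every stage testable without
clinical data. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Pipeline overview

1. **Preprocessing.** Images are contrast-equalized with CLAHE on an
   8×8 tile grid. The clip limit is not fixed by the method description;
   the default is 2.0 (in units of the uniform bin height), exposed in
   configuration. Color images are reduced to the green channel, which
   shows retinal tissue with the best contrast. Training-time
   augmentation is horizontal/vertical flips plus rotation; the training
   loops sample rotations from {0°, 90°, 180°, 270°} so that masks map
   exactly onto the pixel grid, while `augment` itself accepts any angle
   in [0°, 360°).

2. **Vessel segmentation (VSN).** An encoder/decoder network: a
   convolutional downsampling path halving the spatial size per level, a
   transposed-convolution upsampling path, and skip concatenations
   between same-level maps. Two extras distinguish it from a plain
   U-net: a *multi-input module* (the raw image, average-pooled to each
   encoder level's grid, is convolved and concatenated with the features
   entering that level) and a *connected-convolution module* (two
   conv3×3+BN+ReLU stages whose output is concatenated with the block
   input). Training is per-pixel softmax cross-entropy under Adam. The
   published schedule (100 epochs, learning rate 5×10⁻⁶) is kept as the
   configuration default; the desk-scale experiments in this repository
   use a reduced network (3 levels, 8 base channels) trained 20 epochs at
   1×10⁻³ on 64-px phantom patches, which reaches held-out Dice ≈ 0.95+.
   Exact channel widths per level are not published; widths double per
   level from a configurable base. A classical fallback segmenter
   (multiscale Sato vesselness at σ = 1–3 px, Otsu threshold inside the
   circular field of view) lets the pipeline run with no trained weights;
   it infers vessel polarity (dark vessels in color fundus, bright in
   fluorescein angiography) from the background brightness of the raw
   image.

3. **Junction detection (JDN).** An anchor-based detector: a residual
   bottleneck backbone (1×1–3×3–1×1 convolutions with an identity
   shortcut, `out = ReLU(R(x) + I(x))`) produces C1–C5; C3–C5 feed a
   feature pyramid whose top-down path upsamples by 2 with a 3×3
   transposed convolution and merges laterally by element-wise addition,
   followed by a 3×3 anti-aliasing convolution (P3–P5), with P6/P7 from
   stride-2 convolutions. Every pyramid cell carries 6 anchors — scales
   {2⁰, 2^½} × aspect ratios {1, 2, 0.5} — parameterized
   area-preservingly as H = BA·S/√AR, W = BA·S·√AR. (The two formula
   readings coincide at AR = 1; the area-preserving reading is the
   standard anchor parameterization and is pinned by a regression test.)
   The classification subnet is trained with the focal loss
   (γ = 2, α = 0.25, the customary values; they are not printed in the
   method description) and the box subnet with smooth-L1, under momentum
   SGD with cosine learning-rate decay. Decoding applies the regression
   deltas, drops boxes below a score threshold (default 0.05), runs
   non-maximum suppression (IoU 0.3), and caps the output at 200 boxes;
   box centers become candidate junction points. Ground-truth points are
   expanded to square training boxes (default 24 px at a 512-px reference
   scale) since the detector is trained on areas containing junctions.
   Networks are implemented on a small in-package numpy autodiff engine
   (`retinareg.nn`): im2col convolutions, transposed convolutions, batch
   normalization, the detection losses with hand-derived gradients, and
   Adam/momentum optimizers. All gradients are verified against central
   finite differences in the test suite.

4. **Calibration.** A detected landmark is kept only if the vessel
   centerline truly has ≥ 3 branches meeting there. The vessel mask is
   skeletonized (one global thinning — stable under repeated calibration,
   unlike per-crop thinning whose result depends on window placement),
   short spurs are pruned (4 rounds of endpoint deletion), and each
   skeleton pixel's *crossing number* (0→1 transitions around the
   8-neighborhood ring) is computed: interior line pixels score 2,
   endpoints 1, junctions ≥ 3. Crossing number is used instead of a raw
   neighbor count because diagonal adjacency over-counts neighbors.
   Candidates are snapped to the nearest qualifying pixel within a snap
   radius (default 8 px; 0 = filter without moving) inside a search
   window (half-size 12 px); clusters of junction pixels (an X-shaped
   crossing thins into two 3-branch pixels) are canonicalized to one
   representative pixel so snapping is deterministic. Duplicates keep the
   highest score. The same machinery provides a classical skeleton-based
   junction detector used when a trusted vessel mask exists.

5. **Registration.** Each calibrated junction yields a keypoint (plus up
   to 2 auxiliary keypoints at gradient maxima within a 5-px radius —
   the landmark's surrounding region participates, with the count kept
   bounded). Keypoints get dominant orientations from a Gaussian-weighted
   36-bin gradient histogram; all peaks within 80% of the maximum are
   kept (up to 3), as junction patches often have near-tied arm
   orientations. Descriptors are 4×4×8 = 128-dimensional SIFT-style
   orientation histograms sampled on a rotated 16×16 grid, clipped at 0.2
   and renormalized. The descriptor substrate inside `register_pair` is
   the smoothed segmented vessel map rather than raw intensity, making
   matching insensitive to illumination change and to angiography's
   contrast inversion; the keypoint scale default of 3 (≈ 48-px support)
   captures enough branch geometry to survive defocus-induced vessel
   width changes. Matching is nearest/second-nearest Euclidean with
   Lowe's ratio test at 0.84 and a one-to-one filter (lowest distance
   claim per sensed keypoint wins); matching runs one direction
   (reference → sensed). The homography is estimated by RANSAC over
   minimal 4-point projective solves with normalized-DLT re-estimation on
   the consensus set (scikit-image's `ransac`/`ProjectiveTransform`,
   seeded; reprojection threshold 3 px, confidence 0.995, ≤ 2000 trials),
   normalized to h₃₃ = 1, and applied as

       a′ = (h₁₁a + h₁₂b + h₁₃)/(h₃₁a + h₃₂b + 1)
       b′ = (h₂₁a + h₂₂b + h₂₃)/(h₃₁a + h₃₂b + 1)

   mapping sensed pixels into the reference frame; warping is
   inverse-mapped bilinear resampling.

6. **Evaluation.** Confusion-matrix metrics (undefined denominators are
   reported as NaN, not raised), ROC AUC (scikit-learn, cross-checked
   against a brute-force concordance oracle), greedy one-to-one point
   matching at a 5-px tolerance, mean control-point error (median/max
   exposed as options), and the success-rate curve over error thresholds
   0–25 px in 0.1-px steps with AUC normalized by the 25-px span. Failed
   registrations enter the curve as infinite error, counting against
   success at every threshold.

## The synthetic generator

`retinareg.synthetic` grows recursive binary branching trees from root
stubs on the rim of a circular field of view: segments taper by a width
decay per generation, branch with a set probability at half-angles of
25–50°, and may cross vessels from other subtrees at steep angles
(recorded as crossovers). Defaults — 256-px field, 4 roots, branch
probability 0.85, 5-px trunks, decay 0.85, ≤ 7 generations, ≥ 9 px
between junctions — give 10–25 junctions per image, a desk-scale stand-in
for the dozens visible in a full fundus photograph.

Three generator choices matter for interpreting the tests:

* **Geometry hygiene.** Segments that would cross an existing vessel at
  a shallow angle (< 35°), pass tangentially close without crossing, or
  create a junction within the minimum separation are rejected. Real
  vasculature is not so tidy; this guarantees that every junction in the
  rendered mask corresponds to a recorded ground-truth landmark, which is
  what makes exact precision/recall accounting possible.
* **Skeleton-consistent ground truth.** Rasterizing thick vessels moves
  the point where centerlines actually meet a few pixels from the ideal
  polyline vertex, so recorded coordinates are refined to the nearest
  skeleton junction pixel (within 5 px). The ground truth therefore
  describes the drawn image, not the undrawn geometry.
* **Rendering.** Fundus style: dark vessels (−70 gray) on a bright
  textured background with a radial illumination gradient and additive
  noise; angiography style inverts the contrast; the defocused variant
  blurs the sensed frame with a σ = 2 px Gaussian. The reference and
  sensed frames use independent noise/texture seeds, so a registered pair
  differs in illumination and texture, not only in geometry.

Pairs are linked by an exactly known homography composed from rotation
and scale about the image center, translation, and perspective terms
(sensed → reference, h₃₃ = 1); the sensed mask and junctions are the
reference ones pushed through its inverse with nearest-neighbor
resampling.

What the phantoms do **not** emulate: pathology (exudates, hemorrhages),
the optic disc and macula, vessel curvature between branch points,
central reflex, chromatic effects, and resolution above 256 px. Passing
the synthetic suites therefore demonstrates that the algorithms are
implemented correctly and are robust to geometry, illumination,
modality inversion and defocus at desk scale — not that clinical-grade
accuracy would be reached on real databases.

## Numerical choices and degenerate inputs

* Coordinates are 0-based with pixel centers at integers; geometric
  x = column, y = row. Point files are CSV (canonical) or JSON;
  correspondence files are 4-column text, comma- or whitespace-delimited.
* Homographies are always normalized to h₃₃ = 1 and must be invertible;
  a point on the projective horizon raises rather than returning
  garbage.
* RANSAC degeneracy (collinear samples, < 4 inliers) yields status
  `degenerate`; fewer than 4 ratio-test matches yields
  `insufficient_matches`. The pipeline reports these as distinct exit
  codes (2 and 3) instead of raising.
* Flat descriptor patches (zero gradient energy) are invalid and their
  keypoints dropped. Descriptor norms are unit to 1e-6.
* Batch normalization keeps running statistics (momentum 0.1) for
  evaluation mode; training determinism is exact for fixed seeds because
  all initialization and data ordering flow from `numpy.random.default_rng`.
* The desk-scale experiment sizes (50 registration pairs, 20 trees, 200
  training patches, 10 detection images, 20 robustness pairs per
  condition) were chosen so the whole suite replays in a few minutes on
  one CPU core while keeping the pass/fail statistics stable across
  seeds.

## Known limitations

* The numpy networks are desk-scale: the published 50-layer backbone and
  full-resolution training are configurable in principle but impractical
  without GPU acceleration.
* The learned JDN is trained and evaluated here only on binary vessel
  masks (the input variant that performs best in the original study);
  color/grayscale input works but is untested against ground truth.
* `register_pair` assumes both frames show the same eye with overlap;
  wildly disjoint inputs surface as `insufficient_matches` or a large
  error, not as a diagnosed failure mode.
* The success-rate protocol operates in the coordinate units of the
  supplied correspondences; a `--scale` flag converts when annotations
  and images are at different resolutions.
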