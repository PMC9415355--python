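# Methods

## The measurement model

Each specimen is represented by an ordered sequence of grayscale frames
taken while it sinks through a backlit, ethanol-filled cuvette, alternating
between two cameras mounted at right angles. Because the frame rate is
fixed, the number of frames per specimen is inversely proportional to its
sinking speed; real communities span roughly 16–360 frames per specimen.
The specimen appears as a dark, connected silhouette ("blob") on a bright
background.

### Silhouette segmentation and features

Foreground is everything strictly darker than a threshold — Otsu's method
by default (silhouette imaging gives strongly bimodal histograms), or a
fixed value. The largest 8-connected component is kept and its interior
holes are filled, so translucent body parts do not fragment the area proxy.
For efficiency the Otsu histogram is estimated on a 2×-decimated copy of
the frame and the resulting threshold applied at full resolution; on
bimodal silhouette histograms this does not materially move the split point.

Geometric features use 0-based row-major coordinates with inclusive
bounding boxes:

- **area** — foreground pixel count;
- **perimeter** — Euclidean length of the Moore-neighbour outer boundary
  walk (axis steps count 1, diagonal steps √2; one-pixel-wide spurs are
  traversed on both flanks). A solid 10×10 square measures exactly 36.
- **max diameter** — the maximum Feret diameter: the largest pairwise
  distance between boundary pixel centers. For filled sets this equals the
  maximum over all foreground pairs, since diameters are attained on the
  boundary; for blobs with > 400 boundary pixels the computation is
  restricted to the convex hull, which is exact.

The standard crop keeps the full 496-px cuvette width and windows the frame
vertically to 496 px centered on the blob (taller blobs force a taller
output; windows are clamped to the frame and padded with background).

**Body size.** Mean silhouette area across all of a specimen's frames,
converted to mm² with the pixel pitch implied by the cuvette geometry:
10 mm of cuvette width spans 496 px, so one pixel covers
(10/496)² ≈ 4.0646×10⁻⁴ mm².

### Splits

All partitioning happens at specimen level, so no frame of one specimen can
appear in two partitions. The test set holds 10 specimens per taxon, drawn
once and reused by every model in an experiment. Training subsamples for
the learning curve are exactly balanced and *nested*: each taxon's pool is
shuffled once per seed and the first n specimens taken, so the n-specimen
subsample is contained in every larger one and learning curves differ only
by added data. The validation carve-out is stratified per taxon with count
max(1, round-half-up(0.10·n)) — stratification keeps every taxon present in
validation even at the smallest training sizes; the floor of 1 makes the
carve-out defined down to two specimens per taxon. Grouped k-fold deals
each taxon's shuffled specimens round-robin across folds (with a random
rotation so remainders spread), giving per-taxon fold sizes within one of
each other.

### Per-image scoring

Frames are resized to a square side (224 px by convention) and, during
training, randomly augmented in the order rotation → flips → shear. The
shear maps image coordinates (x = column, y = row, origin at the image
center so the specimen is not translated off-frame) through
x′ = x + λₓ·y, y′ = λ_y·x + y; areas scale by |1 − λₓλ_y|. Defaults:
rotation ±180°, flip probability ½ per axis, λ ∈ [−0.2, 0.2]; bilinear
interpolation with constant background padding.

The scorer interface is deliberately minimal — fit on labeled images with
a validation set, then map a frame to an unbounded score vector with one
entry per taxon (no probability squashing). The reference implementation is
a regularized multinomial linear model over a fixed feature map:
pixel-side² block-averaged inverted intensities (16×16 by default, so mass
is positive) concatenated with six blob shape features (log area, log
perimeter, log max diameter, bbox aspect, bbox fill, compactness
perimeter²/area), standardized on the training set. Training is full-batch
gradient descent with momentum 0.9 on the softmax cross-entropy with L2
penalty (1e-3); the step size is set from the logistic Lipschitz bound
0.25·σ_max²(X)/n + λ estimated by power iteration. The problem is convex
and initialization is zero, so training is deterministic without any RNG.
After every epoch the validation loss and accuracy are logged; the returned
weights are the snapshot from the epoch with minimum validation loss, and
training stops once *both* the loss and the accuracy have gone 10 epochs
(patience) without improving, or at 200 epochs. This model is a desk-scale
stand-in behind the same interface a convolutional network would use; it is
not intended to reach CNN-grade accuracy on real imagery.

### Specimen-level decisions

- **majority vote**: each frame casts one vote for its argmax class; ties
  are broken by the larger summed score among the tied classes, then by
  lowest class index (the tie policy is a package decision — deterministic
  and evidence-using).
- **max scoring sum**: argmax of the element-wise sum of the raw unbounded
  per-frame score vectors. Ambiguous frames contribute small scores
  everywhere, so this weighting discounts them automatically.

### Metrics

Accuracy = trace/total of the confusion matrix; per-taxon precision
TPₓ/(TPₓ+FPₓ) and recall TPₓ/(TPₓ+FNₓ); macro values are unweighted means
over taxa with 95 % t-intervals across the per-taxon values (the CI
construction across taxa is a package choice). A taxon that never receives
a prediction has undefined precision; it is reported as 0 with an explicit
flag so macro means stay conservative and auditable.

## The synthetic archive

The generator emulates the statistical structure that drives the analysis,
not the appearance of real animals. Bodies are superellipses
(|u/a|⁴ + |v/b|⁴ ≤ 1; the even exponent renders with integer powers) with
line-segment appendages; taxa differ in mean area (log-spaced 0.5–15 mm²,
a 30× spread), elongation (1.2–4), appendage count (0–6), darkness and
texture noise. A specimen draws its area once from a log-normal
(CV 0.25) and is rendered in every frame at the sensor geometry 700×496 px
(the 496-px width is the cuvette constraint; the height is a free choice
that exercises both crop branches) on a 0.95-intensity background.

Frame counts follow clamp(round(frames_base / sinking_speed), 1, 400);
sinking speeds are geometric over [1, 22.5] by default so the 16-taxon
community reproduces the ~16–360 frames/specimen range, and a narrow
`speed_range` yields communities with comparable frame counts.

Pose is modelled explicitly because it is the mechanism that makes voting
work: the in-plane angle random-walks at 10°/frame and the azimuth about
the vertical axis at 30°/frame (a sinking specimen spins about its long
axis more freely than it pitches). The projected body width at azimuth ψ is
√(cos²ψ + t²sin²ψ) with thickness ratio t ∈ [0.45, 0.85] per specimen, and
the second camera sees ψ + 90° — so alternating frames are orthogonal views
of the same tumbling pose, some strongly foreshortened and genuinely
ambiguous. Specimens also drift downward through the frame (sinking).

Determinism: every specimen's random stream is keyed by a SHA-256 hash of
(master seed, specimen id), so output is byte-identical regardless of
generation order or subsetting.

**What the generator does not emulate**: real morphology (legs, antennae,
segmentation), optics (depth of field, motion blur), debris, occlusions,
specimen-to-specimen shape idiosyncrasy beyond size/thickness, or the true
difficulty of separating congeneric species. Passing the desk-scale tests
therefore demonstrates that the *pipeline* is correct and that its
qualitative behaviour (learning curves, voting dominance) emerges under
realistic structure — not that any particular accuracy carries over to real
archives.

## Desk-scale experiment defaults

The default experiment is 8 taxa × 30 specimens with frames_base = 20 and
speed_range = (0.8, 1.25) (≈16–25 frames per specimen), sweep sizes
{2, 5, 10, 20} against a fixed 10-specimen-per-taxon test set — small
enough to complete in minutes on one CPU while leaving the smallest
training size clearly unsaturated. Cross-validation defaults to the same
validation-fraction rule inside each fold.

## Numerical choices and degenerate inputs

- Round-half-up for validation counts (bit-exact reproducibility).
- Argmax ties always resolve to the lowest class index.
- Frames with no detectable blob are dropped with a logged count; a
  specimen losing all frames is excluded and reported.
- Score vectors containing NaN are rejected rather than silently ranked.
- Shear parameters with λₓλ_y = 1 (singular transform) are rejected.
- Feature standardization guards zero-variance features (divisor 1).

## Known limitations

- The reference scorer is linear; it under-performs a CNN on real imagery
  by design and saturates earlier on hard communities.
- Per-image accuracy is frame-weighted, so communities with very unequal
  frame counts weight taxa unequally in that metric (the specimen-level
  metrics do not).
- The Moore boundary walk measures staircase length, which overestimates
  smooth-contour perimeter by up to ~8 % on diagonal edges; it is used as a
  reproducible convention, not a calibrated length estimate.
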