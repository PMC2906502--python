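# Methods

This note records the models implemented in wormglow, the default parameters and why
they were chosen, what the synthetic-data generator does and does not emulate, the
numerical conventions, and the known limitations. Problem sizes (population counts,
grid resolutions, bootstrap budgets) are this package's own choices, selected so that
every claim can be re-verified on a laptop in minutes.

## Coordinate and intensity conventions

* Points are `(x, y)` with `x` the column and `y` the row; arrays are indexed `[y, x]`.
  The y axis points **down** (image convention), so "left of travel" along a unit
  tangent `(tx, ty)` is `(ty, -tx)`.
* Micrographs hold raw camera counts as float64 and are never rescaled on read; 12-bit
  data in 16-bit containers keeps its values. All quantitative sampling uses raw
  counts. The 8-bit `green` channel of a labeled image (per-image min–max
  normalization) exists only for display and NCC-based registration, where NCC's
  affine invariance makes the normalization harmless.
* Membership masks use three classes — exterior 0, border 1, interior 2 — stored in
  PNG blue as {0, 128, 255}.
* NCC is the *population* Pearson correlation of the flattened pixel pairs. Zero
  variance either raises (`UndefinedCorrelationError`) or returns 0 under the
  `zero_variance="zero"` policy used inside exhaustive searches.

## Pixel classification

* **Equalization**: intensities map through the cumulative histogram,
  `v → ceil(levels·F(v)) − 1` built on the sorted unique values, so arbitrary (e.g.
  12-bit) ranges equalize without binning artifacts. Rank order is preserved up to
  ties.
* **Features**: per-pixel mean and relative standard deviation (population SD / mean,
  0 where the mean is 0) over a 5 × 5 window. Windows are clipped at image borders
  (exact smaller windows, no padded values) — implemented as zero-padded uniform
  filters divided by a pixel-count filter, which is exact and fast.
* **Model**: plain logistic regression on the two features (scikit-learn, C = 1.0).
  Training subsamples at most 200 000 pixels to keep fits instant; the fitted model is
  three floats serialized as JSON.
* **Shape selection**: thresholds 0.05–0.95 in steps of 0.05; for each threshold the
  largest 8-connected component is a candidate; candidates outside 3–25 % of the image
  area are discarded; the most circular (4πA/P², Moore-traced 8-connected contour
  with √2 diagonal steps) wins; circularity ties keep the lowest threshold (largest
  shape). The grid is dense enough that at least one threshold isolates the worm from
  debris whenever the probability map separates them at all.
* **Refinement**: fill holes → 3× erode → 3× dilate (3 × 3 square; removes
  few-pixel-wide noise fringes exactly, and the square element means rectangles are
  preserved) → contour correction. The contour corrector flags contour points farther
  than `d_max = 3` px from the chord through their ±`k = 10` contour-neighbor anchors,
  merges flagged runs separated by fewer than `k` unflagged points (the crown of a
  round protrusion is locally smooth while its flanks are not), drops the runs and
  re-rasterizes the polygon. Rationale for the defaults: an attached egg (a disk of
  radius ≳ 6 px at our rendering scale) deviates from the anchor chord by well over
  3 px and is excised completely, while a genuine body bend of radius R deviates by
  only ≈ k²/2R ≲ 0.3 px, and the worm's thin tapered head stays below the threshold.
  A centered-window PCA formulation was rejected: the maximal deviation of *any*
  ±10-point window from its own principal axis is ≈ 4 px even for a right-angle
  corner, so no attainable `d_max` both fires on eggs and spares smooth contours.

## Meshing anterior/posterior pairs

* Both images are cropped to their worm bounding boxes (offsets tracked so results can
  be mapped back to source frames).
* **Shift search**: level 1 evaluates every integer shift that is a multiple of 16
  within the feasible range (minimum overlap 1000 px); level 2 exhaustively refines
  ±16 px around the five best coarse candidates. Refining around several candidates
  costs little and removes the failure mode where the true peak lies just outside the
  single best coarse cell. Ties prefer the smaller |sx|+|sy|, then (sy, sx) — fully
  deterministic.
* **Brightness harmonization**: least squares `P ≈ gain·A + offset` on the overlap of
  the normalized greens; a constant overlap raises `DegenerateFitError`. The fused
  green averages the overlap after applying the fit to A; the raw-count mosaic is
  combined *without* harmonization because raw counts carry the measurement.
* **QC**: the ratio of mean raw overlap intensities must not exceed 5×, otherwise the
  pair is flagged as an exposure mismatch and excluded from population analysis.
* **Anatomy**: the fused mask is skeletonized (Zhang–Suen-class thinning via
  scikit-image); branched skeletons are reduced to two endpoints by synchronous
  layer-wise endpoint deletion with recorded deletion times, regrowth of the two
  survivors along strictly decreasing times, and a final breadth-first pruning to the
  simple path between the regrown tips. The endpoint inside the anterior-only canvas
  region is the head, the posterior-only one the tail; if both endpoints fall in the
  overlap (curled worm) the specimen requires manual annotation. The vulva side comes
  from backbone convexity: after resampling the backbone to ≤ 50 equidistant points
  (raw skeleton steps are quantized to 8 directions and their turning is dominated by
  pixel zigzag), if ≥ 90 % of the absolute turning mass shares one sign the worm is
  C-shaped and the inner side (right of travel for clockwise turning in the y-down
  frame) is the vulva side; otherwise "unknown" and manual annotation is required.

## Straightening (aligned 2D intensity images)

* The backbone path is resampled to `h` equidistant points (arc length counts
  diagonals as √2); tangents are central differences.
* At each point, perpendicular marches in 0.5 px nearest-neighbor steps find the last
  in-mask positions on both sides; each border-to-border chord is split into `w`
  equal segments. Consecutive chords bound a row of quadrangles, giving an
  `h × w × 4 × 2` corner grid; the terminal row reuses the last chord advanced half an
  arc step along the tangent so exactly `h` rows exist.
* Each cell value is the mean of the raw pixels whose centers fall inside the convex
  quadrangle (boundary inclusive, orientation-normalized half-plane tests); a
  quadrangle too small to contain any pixel center falls back to bilinear
  interpolation at its centroid.
* Default grid 75 × 15 (≈ 1 : 5 aspect like the worm itself); a DIC-resolution preset
  of 520 × 52 exists. `select_resolution` picks the finest candidate grid whose
  replicate-to-replicate NCC has not dropped more than 15 % below the best candidate.
* Orientation: anterior at row 0; if the vulva is on the worm's left, columns are
  mirrored so the vulva side is always the rightmost column.

## Pattern clustering and confidence

* Distance `1 − r²` with r the NCC of two aligned images. Squaring makes the distance
  invariant to *any* affine intensity transform, including inversion — two worms with
  the same spatial pattern at different expression levels are identical to this
  metric. `1 − r` and Euclidean distance are available as controls; Euclidean
  clustering demonstrably groups by mean brightness instead of pattern.
* Agglomerative clustering (scipy linkage; average linkage by default, complete and
  single supported) on the condensed distance matrix; flat labels by `maxclust` cuts.
* **Multiscale bootstrap** (pvclust-style): for scales r = 0.5 … 1.4 (step 0.1) and
  `n_boot` replicates each, `ceil(r·m)` pixel *positions* are drawn with replacement,
  distances recomputed, the tree rebuilt, and each observed node's leaf set counted.
  BP is the count at scale 1. AU comes from the weighted least-squares fit
  `Φ⁻¹(1 − BP_r) = v·√r + c/√r` with binomial-variance weights, `AU = 1 − Φ(v − c)`;
  nodes with degenerate fits (all-0 or all-1 counts) clamp to 0/100 and are flagged.
* Cluster summaries: pixel-wise mean and relative SD maps; NaN relative SD for
  single-member clusters. Correlation matrices are ordered by group label then
  descending row sum, pushing each group's most prototypical worm forward.

## Synthetic worms

The generator is the package's source of ground truth; its defaults define the study
conditions and were fixed before any acceptance outcome was inspected.

* **Geometry**: an analytic backbone of length 400 px (straight, C-shaped with
  constant turn rate, or S-shaped with sign-flipping curvature; total turn ≈ 1.0–2.2
  rad), half-width 11 px tapered as 0.3 + 0.7·√(4u(1−u)) — full width at mid-body,
  rounded ends. Curved poses bend toward the declared vulva side, because a real
  worm's vulva lies on its inner, more strongly curved side; this is what makes the
  convexity rule testable.
* **Intensity**: background 100 counts, body baseline (e.g. 400) plus Gaussian loci
  specified in body coordinates (axial position 0–1, lateral position −1…+1 with +1 on
  the vulva side, amplitude in counts, σs in body units), plus i.i.d. Gaussian camera
  noise (default SD 15). Body coordinates of rendered pixels come from
  nearest-backbone-point lookup (cKDTree) with the sign of the lateral offset from the
  tangent cross product.
* **Ground truth**: mask, backbone, head/tail/vulva anatomy, and the ideal 75 × 15
  pattern the locus model implies.
* **Pairs**: `split_pair` cuts a rendered worm into anterior/posterior parts with a
  known integer shift (multiples of 16 by default), linear brightness mismatch and
  optional extra noise — the exact inverse problem the mesher solves.
* **Populations**: classes Bright (two strong loci, bright baseline), DimA (head
  locus, dim), DimB (tail + mid loci, dim) and All (a random Bright↔Dim mixture with
  intermediate brightness, emulating worms from the middle of the brightness range);
  default counts 16/11/11/22. Per-specimen jitter: locus position (axial SD 0.02,
  lateral SD 0.08), lognormal amplitude scatter (σ = 0.15), pattern noise SD 12.
  `render=False` yields the jittered noisy 75 × 15 patterns directly (what a perfect
  segmentation would measure), which keeps population-scale experiments fast;
  `render=True` rasterizes full micrographs.
* **Not emulated**: optical blur/PSF, autofluorescent gut granules, touching or
  overlapping worms, eggs inside the body, stage drift, uneven illumination. Segmentation
  results on synthetic data are therefore optimistic relative to real micrographs.

## Numerical choices

* All randomness flows through `numpy.random.default_rng` from explicit seeds;
  per-specimen seeds are drawn below 2³¹. Population statistics (SD, correlation) use
  ddof = 0 throughout for consistency with the NCC definition.
* Shift search and quadrangle tests are exact integer/half-plane computations; no
  subpixel interpolation is used anywhere except the explicit bilinear fallback.
* Dendrograms use scipy's linkage matrix format; leaf sets, Newick export (with AU/BP
  node annotations) and cuts are derived from it.

## Limitations

* Vulva-side inference only works for clearly C-shaped worms; straight and S-shaped
  specimens need manual annotation (`ManualAnnotationRequired` is raised, and the CLI
  accepts an annotations CSV). This mirrors the underlying geometric reality, not an
  implementation shortcut.
* The brightness model between image pairs is linear; nonlinear detector response is
  out of scope.
* The contour corrector assumes defects are locally sharp relative to a ±10-point
  contour window; debris fused smoothly over longer scales is not removed.
* AU values from 10 scales × a few hundred replicates carry Monte-Carlo noise of a few
  percentage points; claims near the 95 % threshold should use `n_boot ≥ 1000`.
* Head/tail disambiguation relies on the anterior/posterior capture protocol; for
  single whole-worm images the anatomy must be supplied (generator truth or manual).
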