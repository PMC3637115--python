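# Methods

This note records the models, conventions and numerical choices behind
`fibromet`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Image model and segmentation

Images are single-channel 8-bit grids (`CalibratedImage`): integer
intensities on the 256-level scale (0–255) plus a mandatory physical pixel
size in μm/px. Calibration is never inferred from file metadata; every
length and area converts through the user-supplied pixel size.

**Automated threshold.** `segment.auto_threshold` maximizes the
between-class variance of the (≤ t, > t) histogram split over all integer
levels t ∈ [0, 254] (Otsu's criterion), computed directly on the 256-bin
histogram with vectorized cumulative moments. Pixels *equal* to the level
are background (strict `>`), matching the reading that the threshold "cuts
off" everything at or below the minimum signal intensity. Ties take the
lowest level. A constant image has no two-class split and raises a
degenerate-histogram error. The test suite checks equality against an
exhaustive 255-level scan and against `skimage.filters.threshold_otsu` on
full-range images.

*Known limitation:* a global Otsu threshold presumes a signal is present.
On a signal-free noise image it splits the noise distribution itself, and
at ~50 % foreground density the 8-connected mask percolates into one huge
component that no minimum-size gate removes. Object counting therefore
assumes at least one genuine object per image (or an upstream
contrast/quality gate).

**Minimum object size.** The size gate is calibrated from measured
reference cells (canonically twelve): `min_size = floor(f · min(areas))`
with factor f = 0.5 by default (configurable). Half the smallest genuine
cell rejects debris while passing every reference cell; the factor is a
convention, exposed in `PipelineConfig.min_size_factor`.

**Objects.** ROIs are 8-connected components (the common default of ROI
tools) of at least `min_size` pixels, labelled 1..k in raster order of
their first pixel, each carrying its pixel set and its closed sub-pixel
boundary: the marching-squares iso-contour at level 0.5. Coordinates are
0-based, row-major, origin top-left, pixel centers at integers.

**Surface reconstruction.** The 3-D surface grid is the identity height
map (height = intensity, 0–255), exported at image dimensions for any
surface renderer; no interactive viewer is provided.

## Morphometric indices

All indices derive from the boundary polygon and pixel count:

- **Feret / orthogonal diameters.** The max feret is the largest pairwise
  distance between convex-hull vertices of the boundary (equivalent to a
  rotating-calipers sweep; verified against a 3600-angle projection scan to
  < 0.5 %). The orthogonal diameter is the hull extent projected
  perpendicular to the max-feret axis — the "major orthogonal diameters"
  reading. The alternative min-feret/max-feret convention differs for
  concave shapes and is not used.
- **Circularity** = orthogonal / feret ∈ (0, 1] (discretization may push it
  marginally above 1; a 1.05 ceiling is tolerated). 1 for a circle; the
  elongated Y-like shapes of migratory fibroblasts score ≈ 0.2–0.4.
- **Perimeter** = length of the boundary polygon after smoothing with a
  5-vertex circular moving average. The raw marching-squares contour
  staircases (+6 % on digitized disks, which would bias the complexity
  index); the short smoothing window (~2.5 px of arc) brings disk
  perimeters within 0.5 % of 2πr over radii 10–100 px while leaving
  multi-pixel shape features (arms, lobes) intact. Corner-heavy shapes pay
  a small price: a square's measured diagonal is ~2.5 % short because the
  contour clips corners at 45°.
- **Area** = pixel count × px². **Complexity** = perimeter / area (1/μm),
  exactly 2/r for a disk.

Scale equivariance (lengths ∝ px, areas ∝ px², circularity invariant) and
rotation invariance (< 2 % drift) are enforced by property tests.

## Synthetic still scenes

`synthgen` renders the two observed morphologies with controllable targets:

- **Signet** (rounded): a superellipse at exponent 2 (an ellipse) with
  semi-axes F/2 and cF/2, so the realized feret is 2·(F/2) and circularity
  is c by construction. Exponents above 2 bulge along the diagonals, which
  moves the max caliper off the major axis — measured +4 % feret at
  exponent 2.5 — so the exponent is fixed at the boundary case.
- **Spindle** (elongated, Y-like): a tapering tail limb plus two tapering
  arms meeting at a branch disk; tail tip at −F/2 on the body axis, arm
  tips at (+F/2, ±cF/2). The max caliper then runs tail→arm-tip
  (≤ 1.03·F for c < 0.45) and the perpendicular extent is ≈ cF, keeping
  realized feret within 5 % and circularity within 0.1 of target. Limb
  half-widths taper polynomially (exponent 0.6) from 5.5 % of F.

Both masks are measured back through the package's own segmentation and
morphometry, so the generator's ground truth is stated in exactly the
metric the analysis reports. Scenes place objects on a jittered grid with
disjoint footprints (overlap is an error — objects are discrete), default
764×560 px at 0.5 μm/px so 30–90 μm cells span realistic pixel counts.
Background is additive truncated-Gaussian noise (mean 10, SD 3, clipped to
[0, 255]); object pixels carry their peak intensity noise-free. This is
deliberately not a microscopy simulation: no PSF, photon noise, bleaching,
staining texture or out-of-focus light. Passing recovery tests shows the
measurement chain is correct on images that satisfy its assumptions, not
that segmentation is robust to real staining variability.

## Synthetic time-lapse and tracking

**Motion model.** Each cell takes one step per 12-h segment. Step lengths
are drawn from a normal(μ = `step_mean`, σ = `step_sd`) truncated
*symmetrically* to [0, 2μ], so the population mean step is exactly μ and
the expected 72-h sampled path length is exactly 6μ (one-sided truncation
would bias it upward by ~σ·φ(μ/σ)). Directions are correlated between
consecutive segments: the turn angle is uniform on ±π(1 − p) with
persistence p (default 0.3; p = 1 gives straight lines, p = 0 a fresh
uniform direction each segment). Positions are interpolated linearly to
the 10-min frame cadence (433 frames over 72 h), so sampling at the 12-h
waypoints recovers the drawn step lengths exactly. A proposed segment
endpoint outside the frame margin is redrawn (first with the persistent
turn law, then uniformly); this keeps nuclei in frame without distorting
step lengths, at the cost of an inward direction bias near walls.
Reflecting the walk at borders was rejected because folding positions
shortens sampled waypoint distances and would break the exact path-length
calibration.

**Frames** are rendered lazily and deterministically per (seed, frame
index): truncated-Gaussian background plus uniform-intensity nucleus disks
(default radius 5 μm, intensity 220). Long sequences therefore cost memory
only for the frames actually sampled.

**Tracking.** Nuclei are detected per sampled frame by the same
threshold + size-gate chain (minimum size: half the nominal nucleus area
when an expected radius is given) with intensity-weighted centroids; blobs
over 1.6× the nominal nucleus area log a merged-detection warning (two
nuclei closer than about two radii fuse under a global threshold and
cannot be split). Linking minimizes the total assignment distance between
consecutive timepoints (Hungarian algorithm) with a distance gate (default
100 μm ≈ 3× the largest per-segment mean step); unmatched tracks
terminate, later-appearing detections are ignored, and only tracks
spanning every timepoint are summarized — the analysis describes a fixed
panel of cells followed for the whole recording, so cells lost to the
field (or to a merge) drop out rather than contributing partial paths.

**Displacement convention.** *Total displacement* is the path length over
the sampled waypoints (not the net start-to-end vector): a 72-h recording
sampled every 12 h contributes six step distances. Net displacement is
reported as a secondary column. Velocity is computed per cell
(displacement / elapsed time) and averaged across cells.

**Recovery study sizes.** `displacement_recovery` defaults to 15 cells per
sequence on a 1600×2400 px (800×1200 μm) field, giving ≈ 300–390 μm grid
spacing — comfortably above twice the gate-scale step, the regime in which
identity assignment is reliable. In the paper-matched 382×280 μm still
field, 15 random walkers with 37 μm steps inevitably approach each other
and identity errors become a property of the *experiment*, not the
tracker; the wider field isolates tracker correctness. The acceptance
study uses 20 seeded sequences per motility regime (CTR-like: step
37 ± 14.7 μm; CD-like: 18.83 ± 6.5 μm per 12 h), chosen so the Monte-Carlo
standard error of each group mean is ≈ 1 μm.

## Statistics

- Summaries: mean, sample SD (n−1 denominator — the convention for
  biological replicates), n, median, range.
- Comparisons: classical one-way ANOVA (between/within mean squares,
  F(k−1, N−k)); `scipy.stats.f_oneway` does the computation, with the
  degenerate cases defined explicitly (all values identical: F = 0, p = 1;
  distinct constant groups: F = ∞, p = 0). For two groups F = t² of the
  pooled-variance t-test, used as an independent cross-check. No
  multiple-testing correction is applied (each parameter is tested alone);
  the run manifest flags this.
- Power simulation: groups are redrawn from truncated normals at published
  mean ± SD (circularity in (0, 1], lengths/areas > 0 — physically valid
  supports whose truncation is negligible at the published parameters;
  note the truncated law's realized moments differ slightly from the
  nominal ones). Reported: rejection rate at α and median p. Under the
  null the rejection rate calibrates to α within binomial error.
- Enzymatic (transglutaminase) activity: (OD₄₅₀ − blank) / cell count
  × 10⁴ — the 10⁴-cell scale is purely a readability convention; fold
  change is the ratio of group means.

## Determinism and I/O

Every stochastic path takes an integer seed (numpy `default_rng`);
identical seeds and parameters give bit-identical images, sequences, draws
and CSV outputs. TIFF/PNG round-trip losslessly; JPEG is read-only with a
logged warning about compression artifacts. The pipeline driver writes a
JSON manifest with the configuration, package version, timestamp and a
SHA-256 hash of every output file.

## Known limitations

- Global thresholding only; no illumination-field correction, no
  per-object adaptive thresholds, no separation of touching objects
  (no watershed) — merged objects are flagged, not split.
- The motility model is a segment-wise persistent walk, not a continuous
  stochastic process; sub-12-h kinetics are linear interpolation and carry
  no information.
- Synthetic imagery validates the measurement chain, not robustness to
  real microscopy artifacts (see above).
- Shape time-courses assume the tracked object is measurable at the
  requested times; unmatched cells are skipped with a warning rather than
  interpolated.
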