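# fibromet

Quantitative image analysis for cultured-fibroblast comparison studies:
fluorescence-signal morphometry from still images and nucleus-tracking
motility analysis from 72-hour time-lapse recordings, with a fully
ground-truthed synthetic-data generator for end-to-end validation.

## The scientific problem

Fibroblasts cultured from duodenal biopsies of celiac patients differ from
healthy controls in the intracellular distribution of extracellular-matrix
proteins (type I/IV collagen, transglutaminase type 2) and in their motility.
Celiac cells tend toward a rounded, ring-like ("signet") fluorescence
pattern while controls show an elongated, Y-like ("spindle") geometry, and
celiac cells migrate roughly half as far over 72 hours. Comparing such
populations requires a reproducible measurement chain:

1. **Segmentation.** A global automated threshold (Otsu's between-class
   variance criterion on the 0–255 intensity histogram) separates signal
   from background; 8-connected components above a calibrated minimum pixel
   size (half the smallest of a set of reference cell areas, by default)
   become regions of interest. The intensity grid itself is exported as a
   height field for 3-D surface reconstruction.
2. **Morphometry.** Per object, with pixel size (μm/px) as the only
   calibration:
   - *feret* — maximum caliper diameter `F = max‖p−q‖` over boundary hull
     points, and the *orthogonal* diameter `O` measured perpendicular to
     the max-feret axis;
   - *circularity index* `c = O / F` (1 for a circle, ≪ 1 for migratory
     Y-shaped cells);
   - *perimeter* `P` (smoothed sub-pixel contour length) and *area* `A`
     (pixel count × px²);
   - *complexity index* `x = P / A` (1/μm; 2/r for a disk of radius r,
     large for thin branched outlines).
3. **Motility.** Frames recorded every 10 min for 72 h are sampled every
   12 h; nuclei are detected per sampled frame and linked across timepoints
   by minimum-total-distance assignment with a distance gate. Per cell,
   *total displacement* is the path length over the seven 12-h waypoints
   and *velocity* = displacement / 72 h. Shape indices can be re-measured
   at 0/36/72 h along the tracks.
4. **Statistics.** Groups are summarized as mean ± SD (n−1) and compared by
   one-way ANOVA (significance at p < 0.05; for two groups F = t²).
   A power-simulation utility redraws groups from published mean ± SD
   parameters (truncated normal) to check printed significance bounds, and
   ELISA-style enzymatic activity is normalized per 10⁴ cells.

Because studies of this kind rarely deposit raw images, the `synthgen`
module generates the inputs with known ground truth: still scenes of
spindle/signet cells on noisy 8-bit backgrounds (default 764×560 px at
0.5 μm/px), and time-lapse sequences in which nuclei execute a persistent
random walk whose per-12-h step length distribution is exactly calibrated
(population mean path length = 6 × step mean over 72 h).

## Worked example

```python
from fibromet import morpho, segment, synthgen

truth = synthgen.random_scene_truth(n_spindle=2, n_signet=3, seed=42)
scene = synthgen.render_scene(truth)
level, mask = segment.auto_threshold(scene.image)
rois = segment.detect_objects(mask, min_size=200)
records = morpho.measure_objects(scene.image, rois)
print(f"threshold level: {level}; objects detected: {len(rois)}")
print(morpho.records_to_frame(records).round(2).to_string(index=False))
```

prints

```
threshold level: 25; objects detected: 5
 label  feret_um  orthogonal_um  perimeter_um  area_um2  circularity  complexity
     1     33.56          29.16         98.01    755.75         0.87        0.13
     2     29.60          26.38         87.23    599.75         0.89        0.15
     3     31.53          23.54         85.94    567.75         0.75        0.15
     4     56.57          21.71        150.20    297.25         0.38        0.51
     5     58.69          10.86        140.80    301.00         0.19        0.47
```

Objects 1–3 are the rounded signet cells (short feret, circularity near
0.9, low complexity); objects 4–5 are the elongated spindle cells (long
feret, circularity 0.2–0.4, perimeter-dominated complexity ≈ 0.5 /μm) —
the two morphological regimes the indices are designed to separate.

The motility side, end to end on synthetic recordings (15 cells per
sequence, steps of mean 37 μm per 12 h):

```python
from fibromet import motility

df = motility.displacement_recovery(step_mean=37.0, step_sd=14.7,
                                    n_sequences=3, seed=1)
print(f"mean total displacement: {df.total_displacement_um.mean():.1f} um")
print(f"mean velocity: {df.velocity_um_per_h.mean():.2f} um/h")
```

prints

```
mean total displacement: 222.2 um
mean velocity: 3.09 um/h
```

i.e. the tracking pipeline (detection → gated assignment → path length)
recovers the generator's calibrated 6 × 37 = 222 μm to within sampling
error.

A command-line interface mirrors the library (`fibromet generate scene`,
`fibromet segment`, `fibromet measure`, `fibromet track`,
`fibromet stats compare|power`, `fibromet run --config config.yaml`).

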