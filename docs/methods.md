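# Methods

## Pipeline model and assumptions

The package treats adipocyte sizing as a fixed-sequence raster pipeline
on calibrated 8-bit grayscale images. The model of the tissue is simple
and deliberate: bright, near-circular lipid lumens separated by thin
dark membranes, with slide-level variation in illumination and staining
intensity. Every stage is deterministic; identical input and parameters
produce identical output, and each raster operator has a single
documented convention so independent re-implementations can match it
bit-exactly.

### Grayscale conversion

Colour input is reduced with the unweighted channel mean
`round((R+G+B)/3)`, half-up rounding. No stain-specific weighting is
applied by default because the pipeline only needs lumen/membrane
contrast, which survives any monotone channel mixture; ITU-R 601 luma
weights are available (`to_8bit_gray(..., weights=REC601_WEIGHTS)`) for
sensitivity analysis.

### Triangle threshold

The Zack triangle method runs on the 256-bin histogram with
dark-background polarity: the line is drawn from the modal bin to the
farthest nonzero bin on the bright side, and the returned level is the
bin maximizing perpendicular distance to that line. Conventions fixed
here: ties resolve to the lowest bin; the comparison applied to pixels
is strict (`intensity > level` is foreground); a single-populated-bin
histogram returns that bin; an empty histogram raises. The output is
invariant to uniform scaling of counts. Because the inclusive/exclusive
and side conventions of other implementations vary, levels may differ
from them by a gray level or two on the same image; this is a
documented convention difference, not an error.

### Binary cleanup

Erosion uses a 3×3 square structuring element, out-of-bounds treated as
background, one iteration per pass (`erode_iterations_per_pass` in
`SegmentationParams`). Outlier removal mirrors a median-based
despeckler: the kernel is the set of integer offsets with Euclidean
distance ≤ radius (21 pixels at 2.5, 97 at 5.5); border neighbourhoods
are clamped to the image, and the even-sized clamped neighbourhoods use
the lower median, again so that oracles can match exactly. Only
brighter-than-median outliers are replaced (`which="bright"`), so on a
binary mask the operation removes foreground specks and protrusions but
never fills gaps. Internally the interior is computed with a fast rank
filter and the border band recomputed under the clamped definition.

The full sequence is threshold → erode → outliers(2.5) → erode →
outliers(5.5), with a manual threshold override available for slides
where the automatic level fails (see QC below).

### Particle measurement

Components are 8-connected (configurable to 4). Area is the component
pixel count times the pixel area; interior holes are excluded by
default (`include_holes=True` fills them). Perimeter is measured as the
length of a resampled polygon along the component's outer half-level
boundary contour: the 0.5-level contour is traced (diagonal-connected,
matching the labeling), every 4th vertex kept, and the closed polygon
length summed. The resampling step is the load-bearing choice: the raw
staircase boundary of a digitized smooth shape overestimates true
perimeter by ~5%, which would push the circularity of a perfect disk
down to ~0.90 and visibly distort the 0.63 circularity gate, while
standard corner-weighted corrections (Kulpa, Vossepoel–Smeulders)
over-shorten genuinely cornered shapes. A 4-vertex chord (~2.8 px) is
short against any retainable cell's radius (≥ 20 px at 0.5 µm/px):
measured circularity is 0.99 for a radius-100 disk and 0.81 for a
50-pixel square (continuous value π/4 ≈ 0.785). Circularity is capped
at 1.0, which also absorbs degenerate coarse shapes (a single pixel's
diamond contour yields 4πA/P² > 1).

Gates default to the macro values — area 315–40000 µm², circularity
0.63–1.00, edge exclusion on — and are inclusive at both ends. Objects
failing the upper area gate are excluded, never split: oversized
objects are taken to be merged cells with damaged membranes, whose
"size" is not meaningful. If a slide is processed in tiles, edge
exclusion is only correct when tiles overlap by at least one cell
diameter; the package does not tile automatically.

### Diameters, QC and consolidation

Retained areas become equivalent circular diameters `2·√(A/π)`,
reported at full precision; sample SD uses the n−1 denominator. QC is
driven by the retained (post-gate) cell count — the gated count is used
rather than the raw component count, since the gates define what counts
as a detected cell: ≥ 200 `ok`, 100–199 `inspect`, < 100 `excluded`.
`inspect` samples keep their statistics but carry the flag; the human
decision after inspection is expressed by re-running with
`rethreshold_sample` (recorded via the `rethresholded` flag), not
automated. Excluded samples keep a row in the consolidated summary for
the audit trail, with blank mean/SD, and contribute nothing to the
long-format diameter table.

## Method-comparison statistics

Differences are oriented automated − manual throughout. Limits of
agreement use the conventional 1.96 normal quantile (not a t-quantile),
making them exactly symmetric about the mean difference. Paired t on
zero-variance differences follows a documented convention: all-zero
differences give t = 0, p = 1; constant nonzero differences give a
signed infinite t rather than an exception. Meng's Z for correlated
correlations Fisher-transforms both coefficients and uses
r̄² = (r1²+r2²)/2, f = min(1, (1−r12)/(2(1−r̄²))), h = (1−f·r̄²)/(1−r̄²),
Z = (z1−z2)·√((n−3)/(2(1−r12)h)); f is clipped at 1 per the original
method. The inter-method correlation r12 is always an explicit input —
it cannot be recovered from the two criterion correlations alone. All
p-values are two-sided.

HOMA-IR is insulin (µU/mL) × glucose (mmol/L) / 22.5. VAI uses the
validated sex-specific equations (male: WC/(39.68+1.88·BMI) ×
TG/1.03 × 1.31/HDL; female: WC/(36.58+1.89·BMI) × TG/0.81 × 1.52/HDL)
with WC in cm, BMI in kg/m², TG and HDL in mmol/L.

## Synthetic tissue generator

The generator exists to make the pipeline falsifiable without slides:
it emulates the features the pipeline depends on — bright lumens
(default intensity 220) on a membrane-toned background (80), diameters
from a truncated normal (defaults 65 ± 10 µm, bounds 20–225 µm,
matching both the scale of human adipocytes and the pipeline gates),
non-overlapping placement by dart throwing with a minimum separation of
the two radii plus the membrane thickness (2.5 µm), low-order radial
harmonics (amplitude 5% of radius) so circularity is realistic rather
than exactly 1, additive Gaussian staining noise (SD 8 gray levels) and
a 10% linear illumination gradient. The default canvas is 4000×4000 px
at 0.5 µm/px with 300 cells. A configurable fraction of cells is
rendered "damaged": placed as overlapping pairs whose merged lumens
form one oversized, low-circularity object — the situation the upper
area gate exists for. An optional H&E-like RGB rendering exercises the
colour-conversion path. Everything is reproducible from a single seed,
and the exact centre/diameter of every cell is returned.

What the generator does *not* emulate: fibrosis, immune infiltrates,
nuclei, crown-like structures, tissue folds, out-of-focus regions, or
scanner compression artefacts. Passing tests therefore demonstrate
correctness of the measurement chain and its failure modes under
controlled degradation — not clinical-grade robustness on real slides.

## Numerical and degenerate-input choices

- Thresholding an empty (uniform) image yields an empty mask, never an
  exception; the degenerate-histogram error is reserved for literally
  all-zero histograms.
- A sample with zero retained cells is `excluded` with NaN mean/SD.
- `area_to_diameter` rejects non-positive areas.
- TIFF calibration precedence is explicit override > resolution tags
  (inch or centimetre units); a missing or unit-less calibration is an
  error rather than a silent default, since every µm² gate would be
  corrupted by a wrong pixel size. Only the first (highest-resolution)
  page of a multi-page TIFF is read.

## Problem sizes used in the validation suite

The full-scale recovery fixture is 4000×4000 px (2×2 mm at 0.5 µm/px)
with 300 cells, the scale at which edge effects and gate interactions
are all exercised; QC-band fixtures use 1024×1024 px at 1 µm/px with
40 ± 6 µm cells at three cellularities (60/150/260 target cells)
chosen to land safely inside the three QC bands. Operator/oracle
equivalence runs on 100 random 64×64 rasters per operator.

## Known limitations

- The two erosion passes bias diameters low by roughly one pixel of
  radius each (~2.4 µm at 0.5 µm/px on the default fixture, ~4%
  relative). This is a property of the fixed operator sequence itself,
  consistent with automated methods reading systematically smaller than
  manual tracing; no compensation is applied.
- Detection recall degrades monotonically with staining noise only up
  to the threshold-collapse point (noise SD ≈ 40 at default contrast).
  Beyond it, zero-clipping makes bin 0 the histogram mode, the
  threshold collapses, and — counter-intuitively — extreme speckle is
  then partly removed by the erosion passes, so recall is not globally
  monotone in noise. The generator's realistic regime (SD ≤ ~30) is the
  one the property tests cover.
- Merged cells are excluded, not split; no watershed or shape-prior
  separation is attempted.
- Only the mean (and SD) of the diameter distribution is summarized;
  bimodality and large/small-cell splits are out of scope.
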