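# adiposizer

Automated adipocyte sizing from H&E-stained whole-slide images, for
researchers quantifying white adipose tissue morphology (adipocyte
hypertrophy is a widely used marker of adipose tissue function and
cardiometabolic risk). The package is an open, scriptable
re-implementation of a fixed image-analysis macro pipeline, together
with the statistics used to validate an automated sizing method against
manual measurement, and a synthetic tissue generator that makes the
whole pipeline testable against known ground truth.

## The method

White adipocytes appear in H&E sections as large, nearly circular,
unstained lipid lumens bounded by thin eosin-stained membranes. The
pipeline measures them with a fixed operator sequence:

1. **Grayscale** — colour slides are reduced to 8-bit intensities.
2. **Triangle (Zack) auto-threshold**, dark-background polarity: a line
   is drawn from the histogram peak to its far bright tail; the
   threshold is the bin farthest (perpendicularly) from that line.
   Bright lumens become mask foreground.
3. **Binary cleanup** — 3×3 erosion, circular bright-outlier removal at
   radius 2.5 px (replace a pixel by its neighbourhood median if it
   exceeds the median by more than 50), a second erosion, a second
   outlier pass at radius 5.5 px.
4. **Particle analysis** — 8-connected components are measured in
   physical units and gated: area 315–40000 µm², circularity
   `4πA/P²` in 0.63–1.00, border-touching objects excluded. The area
   gates correspond to equivalent circular diameters of 20 and 225 µm;
   objects above 225 µm usually mean collapsed membranes merging two or
   more cells.
5. **Diameters and QC** — retained areas become equivalent circular
   diameters `d = 2·√(A/π)`; a slide with ≥ 200 retained cells passes,
   100–199 is kept but flagged for visual inspection (with a manual
   re-threshold hook), and < 100 is excluded from summary statistics.

Method validation uses Bland-Altman limits of agreement
(mean difference ± 1.96 SD of the paired differences), paired t-tests,
Pearson/Spearman correlations, and Meng's Z-test for comparing the
correlations of two methods with a common criterion. The clinical
indices HOMA-IR (`insulin × glucose / 22.5`) and the sex-specific
visceral adiposity index (VAI) are included for validation against
metabolic markers.

## Worked example

```sh
python examples/size_synthetic_slide.py
```

```
threshold chosen automatically : 104
cells retained                 : 296 (QC: ok)
mean diameter, measured        : 63.4 µm ± 10.2 (SD)
mean diameter, ground truth    : 66.1 µm
detection recall               : 0.987
mean signed diameter error     : -2.60 µm
```

A 4000×4000 px synthetic section (0.5 µm/px) with 300 cells drawn from
a truncated N(65, 10²) µm diameter distribution is segmented and
measured. 296 cells pass the gates (≥ 200, so QC status `ok`); 98.7% of
the true cells are recovered, and the measured mean sits ~2.6 µm below
truth — the systematic footprint of the two erosion passes in the fixed
cleanup sequence, mirroring the automated-reads-smaller offset seen
when such pipelines are compared with manual tracing.

Other entry points: `examples/batch_qc.py` (multi-slide QC and
consolidation), `examples/compare_methods.py` (agreement statistics),
`examples/clinical_indices.py` (HOMA-IR/VAI), and the `adiposizer` CLI
(`run`, `rethreshold`, `compare`, `indices`, `fixture`) for shell use
on directories of TIFF slides.

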