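"""Size one synthetic adipose slide and compare against ground truth.

Generates a 2×2 mm H&E-like section with 300 cells of known diameter,
runs the full measurement pipeline (triangle threshold, binary cleanup,
gated particle analysis) and reports how well the known cell population
is recovered.
"""

from adiposizer import TissueParams, generate_tissue, match_to_ground_truth, process_sample

params = TissueParams(seed=1)  # 4000×4000 px at 0.5 µm/px, 300 cells ~N(65, 10²) µm
image, truth = generate_tissue(params)
measurement, particles, retained = process_sample(image, "demo-slide")

result = match_to_ground_truth(retained, truth)
print(f"threshold chosen automatically : {measurement.threshold_used}")
print(f"cells retained                 : {measurement.n_cells} (QC: {measurement.qc_status})")
print(f"mean diameter, measured        : {measurement.mean_diameter:.1f} µm "
      f"± {measurement.sd_diameter:.1f} (SD)")
print(f"mean diameter, ground truth    : {truth.cells.diameter_um.mean():.1f} µm")
print(f"detection recall               : {result.recall:.3f}")
print(f"mean signed diameter error     : {result.mean_signed_error_um:.2f} µm")

# The measured mean sits a few percent below truth: two 3×3 erosions in
# the cleanup sequence shave roughly one pixel of radius each, a known
# systematic of the fixed operator sequence.
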