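"""Fiber-orientation and anisotropy maps from a simulated scan.

Runs the full chain (q_opt selection, segmentation, row-wise background
subtraction, point-symmetry completion, azimuthal circular statistics)
and compares recovered orientations with the simulator's ground truth.
"""

import numpy as np

import scansaxs as sx

spec = sx.SceneSpec(seed=21)  # default 64x64 scene, three cells
stack, truth = sx.generate_scan(spec)

result = sx.analyze_scan(stack, sx.BackgroundRegion(0, 0, 10, 10),
                         sx.PipelineConfig(a_min=200))

q2, q_opt = result.maps.q_range
print(f"orientation q-range: [{q2:.3f}, {q_opt:.3f}) nm^-1")
print(f"cells annotated: {result.cell_labels.n_cells}")

cyto = truth.cell_mask & ~truth.nuclei_mask
err = result.maps.orientation[cyto] - truth.orientation[cyto]
err = np.abs((err + 90.0) % 180.0 - 90.0)
print(f"median |orientation error| in cytoplasm: {np.nanmedian(err):.2f} deg")

for rec in result.cell_anisotropy:
    print(f"  cell {rec.label}: n={rec.n_selected:4d} "
          f"mean anisotropy {rec.mean:.3f} "
          f"(quartiles {rec.q25:.3f}/{rec.q50:.3f}/{rec.q75:.3f})")

# The per-cell means rank-order with the injected anisotropic fractions
# (0.85, 0.78, 0.70; watershed label numbers follow nucleus raster
# order, not that list). Orientation errors of a fraction of a degree
# to a few degrees reflect the Poisson noise at millisecond exposures.
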