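"""Measure femoral neck width from an 85-point hip outline.

Generates a synthetic landmark annotation whose neck contours are exactly
31.7 mm apart (a typical adult population mean), measures it, then repeats with
0.1 mm landmark jitter to show the measurement noise.
"""

import numpy as np

from fnwpipe import geometry, synth

ann = synth.simulate_shape_annotation(target_fnw_mm=31.7, pixel_spacing=0.5,
                                      jitter_sd=0.0, seed=1)
width = geometry.compute_fnw(ann)
print(f"exact annotation:   FNW = {width.fnw_mm:.4f} mm "
      f"(realized between point {width.point_index + 1} of the "
      f"{width.side_order.split('-')[0]} contour and the opposite segment)")

recovered = [
    geometry.compute_fnw(
        synth.simulate_shape_annotation(31.7, 0.5, jitter_sd=0.1, seed=s)
    ).fnw_mm
    for s in range(100)
]
print(f"with 0.1 mm jitter: mean recovered = {np.mean(recovered):.3f} mm, "
      f"SD = {np.std(recovered):.3f} mm over 100 annotations")
print("The minimum point-to-segment distance between the inferior (points "
      "6-12) and superior (points 32-38) neck contours, in mm, is the FNW "
      "phenotype that all downstream genetics consumes.")
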