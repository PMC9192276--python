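"""Classify voxels against slice contours: the tri-state function f(a, b, c).

Every voxel is labeled -1 (outside all contour lines of its slice), 0 (on a
contour line) or +1 (inside).  The even-odd rule keeps the lumen of a hollow
organ outside; the literal any-polygon rule would fill it.
"""

import numpy as np

from ctsurf import classify_voxels, contours_from_grid, make_bladder_phantom, voxelize

phantom = make_bladder_phantom(lesion_count=0, seed=0)
grid = voxelize(phantom, (48, 48, 48), (1.05, 1.05, 1.05), (-24.675, -24.675, -24.675))
contours = contours_from_grid(grid)

for rule in ("even-odd", "any"):
    field = classify_voxels(grid.dims, contours, grid.spacing, grid.origin, rule=rule)
    inside = int((field.labels == 1).sum())
    volume = inside * grid.voxel_volume
    print(f"rule={rule:8s}: {inside} inside voxels -> {volume:.0f} mm^3")

print(f"wall-only ground truth: {phantom.analytic_volume:.0f} mm^3")
print("(the 'any' rule also counts the lumen, which is why its volume is larger)")
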