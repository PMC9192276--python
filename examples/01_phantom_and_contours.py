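"""Build a synthetic bladder phantom and draw its per-slice contour lines.

A hollow ellipsoidal wall with one papillary lesion is sampled on a CT-like
grid; each axial slice is then contoured at the zero level, giving the
closed polygons L1..Ln that drive voxel classification downstream.
"""

from ctsurf import contours_from_grid, make_bladder_phantom, voxelize

phantom = make_bladder_phantom(lesion_count=1, lesion_radius=4.0, seed=7)
print(phantom.description)
print(f"ground-truth volume: {phantom.analytic_volume:.0f} mm^3 (numeric estimate)")
print(f"ground-truth area:   {phantom.analytic_area:.0f} mm^2 (numeric estimate)")

grid = voxelize(phantom, dims=(64, 64, 64), spacing=(0.8, 0.8, 0.8),
                origin=(-25.2, -25.2, -25.2))
contours = contours_from_grid(grid)

n_polys = sum(len(s.polygons) for s in contours.slices)
print(f"{len(contours.slices)} slices carry contours, {n_polys} polygons total")
mid = contours.polygons_by_slice().get(32, [])
print(f"mid slice has {len(mid)} polygons "
      "(outer wall + lumen boundary, plus any lesion cross-section)")
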