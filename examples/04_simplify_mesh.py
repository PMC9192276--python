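"""Simplify a reconstructed surface with the priority-function edge collapse.

Each candidate edge s is scored Y(s) = Ct*T(s) + Cx*X(s) + Cg*G(s) —
flatness, shape and normalized length — and the cheapest valid edge is
collapsed to its midpoint until the face budget is met.  Topology
(watertightness, Euler characteristic) is preserved by the link condition.
"""

from ctsurf import (SimplifyConfig, classify_implicit, decimate, extract_surface,
                    make_sphere, mesh_stats, voxelize)

grid = voxelize(make_sphere(12.0), (33, 33, 33), (1, 1, 1), (-16, -16, -16))
mesh = extract_surface(classify_implicit(grid))
before = mesh_stats(mesh)
print(f"input:  {before.n_faces} faces, volume {before.enclosed_volume:.1f} mm^3")

for ratio in (0.5, 0.2, 0.1):
    out = decimate(mesh, SimplifyConfig(Ct=1.0, Cx=1.0, Cg=1.0, target_ratio=ratio))
    st = mesh_stats(out)
    dv = (st.enclosed_volume - before.enclosed_volume) / before.enclosed_volume * 100
    print(f"ratio {ratio:.1f}: {st.n_faces:5d} faces, chi={st.euler_characteristic}, "
          f"watertight={st.watertight}, volume change {dv:+.2f}%")
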