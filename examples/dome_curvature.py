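"""Mean curvature of the initial dome.

Builds the cylinder-plus-hemisphere phase field, triangulates its zero
level set and samples the mean curvature along the meridian.  The lateral
cylinder wall has H = 1/(2R), the hemispherical cap H = 1/R; the sharpest
change sits at the junction, which is where the first whorl of organ
primordia emerges in the coupled simulation.
"""

import numpy as np

import phyllosim as ps

grid = ps.GridSpec()
p = ps.MechParams()  # R = 10, Hz = 6
phi = ps.initialize_domain(grid, p)

mesh = ps.extract_isosurface(phi)
H = ps.surface_mean_curvature(phi, mesh)
z = mesh.vertices[:, 2]

print(f"surface: {mesh.n_vertices} vertices, {len(mesh.faces)} triangles")
print(f"{'height z':>9} {'median H':>9}   (1/2R = {1/(2*p.R):.3f}, 1/R = {1/p.R:.3f})")
for z0 in range(1, 16, 2):
    sel = np.isfinite(H) & (np.abs(z - z0) < 1.0)
    if sel.any():
        print(f"{z0:9d} {np.median(H[sel]):9.3f}")
print(f"junction (sharpest H change) is near z = Hz = {p.Hz}")
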