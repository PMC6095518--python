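"""Turing linear stability of the BVAM morphogen system.

Computes, for each value of the domain-size parameter eta used in the
whorl simulations, the unstable wavenumber band, the fastest-growing
wavenumber, and the spherical-harmonic degree that wavelength selects on
a dome of radius 10.  Larger eta -> shorter wavelength -> higher degree,
which is how the simulator's whorl symmetry is steered.
"""

import numpy as np

import phyllosim as ps

RADIUS = 10.0

print(f"{'eta':>7} {'k2 band':>22} {'k2*':>8} {'wavelength':>11} {'degree l':>9}")
for eta in (0.2014, 0.2601, 0.3902, 0.5676, 0.6504, 0.8437):
    p = ps.BVAMParams(eta=eta)
    lo, hi = ps.turing_band(p)
    k2 = ps.fastest_wavenumber(p)
    mode = ps.predict_sphere_mode(p, RADIUS)
    print(f"{eta:7.4f} ({lo:8.4f}, {hi:8.4f}) {k2:8.4f} "
          f"{2 * np.pi / np.sqrt(k2):11.2f} {mode:9d}")

print()
print("With equal diffusivities (D = 1) the instability disappears:")
print("  band =", ps.turing_band(ps.BVAMParams(eta=0.3902, D=1.0)))
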