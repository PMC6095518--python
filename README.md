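# phyllosim

A 3D mechanochemical phase-field simulator of phyllotaxis — the regular
arrangement of repeated plant organs (leaves, floral parts, cactus ribs)
around the growing tip of a shoot.

Phyllotactic patterning happens at the shoot apical meristem (SAM), a
dome of tissue whose surface mechanics and auxin distribution feed back
on each other: auxin softens the cell walls and lets a new organ bulge
out, while mechanical stress orients the transport that redistributes the
auxin. `phyllosim` implements this loop as a coupled PDE system on a
regular 3D grid:

* **Tissue surface** — a phase field φ (+1 inside, −1 outside; the tissue
  surface is the φ = 0 level set) evolving by conservative Cahn–Hilliard
  dynamics under the free energy

  F = ∫ ( Φ_SC²[φ,u] − ½ ϱ_φ|∇φ|² − ½ ϱ_u|∇u|² ) dV,
  Φ_SC = −φ + φ³ − ϵ²∇²φ − ϵ C₀[u] (φ² − 1),

  where C₀ = β u² is a morphogen-dependent spontaneous curvature that
  acts only on the interface (the (φ²−1) factor vanishes in bulk).

* **Morphogens** — an activator–inhibitor pair (u, v) with BVAM kinetics,

  ∂u/∂t = D∇²u + η(u + a v − c u v − u v²),
  ∂v/∂t = ∇²v + η(b v + h u + c u v + u v²),

  which undergoes a Turing instability; η plays the role of domain size
  and selects the pattern wavelength (hence the whorl symmetry), while c
  interpolates between spot (c = 0.57) and stripe (c = 0) regimes.

* **Coupling** — u feeds the surface through the spontaneous curvature,
  through a mass-addition term m u², and through a Gaussian tip-growth
  source; the surface feeds back on u because its stress tensor σ_αβ
  (derived from the same free energy) acts as the anisotropic diffusion
  mobility of u: ∂u/∂t ⊃ γ ∇·(σ ∇ δF/δu).

On a growing dome (cylinder of radius R = 10 capped by a hemisphere) the
coupled dynamics produces whorled, spiral and ribbed arrangements; the
analysis layer extracts the surface, maps its mean curvature, detects and
fixes auxin-accumulation sites (primordia), and classifies the pattern
and its fold symmetry.

## Worked example

`examples/turing_stability.py` prints the linear-stability picture that
steers every simulation:

```
    eta                k2 band      k2*  wavelength  degree l
 0.2014 (  0.0645,   0.1219)   0.0889       21.08         2
 0.2601 (  0.0834,   0.1574)   0.1148       18.55         3
 0.3902 (  0.1251,   0.2362)   0.1722       15.14         4
 0.5676 (  0.1819,   0.3436)   0.2505       12.55         5
 0.6504 (  0.2084,   0.3937)   0.2870       11.73         5
 0.8437 (  0.2704,   0.5107)   0.3723       10.30         6

With equal diffusivities (D = 1) the instability disappears:
  band = None
```

Each row gives the unstable band of squared wavenumbers, the
fastest-growing k², the corresponding wavelength in grid units, and the
spherical-harmonic degree l whose eigenvalue l(l+1)/R² lies closest to k²
on a dome of radius 10 — i.e. the expected number of organs around the
axis. A full coupled run is in `examples/whorl_simulation.py`; at
η = 0.2014 it fixes a first generation of primordia whose azimuthal fold
symmetry is 2, matching the two-whorled arrangement this parameter set
produces, and `examples/dome_curvature.py` shows where the surface mean
curvature changes most sharply (the cylinder–hemisphere junction), which
is where organs emerge.

Other entry points: `examples/pattern_sweep.py` (phase-diagram tables),
`examples/long_horizon_whorls.py` (multi-generation run, not desk scale),
and a thin CLI (`phyllosim run|sweep|analyze|stability|fixtures`) over
YAML configs, HDF5 snapshots, VTK/PLY exports and CSV tables.

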