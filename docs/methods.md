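# Methods

## Model

The simulator couples two processes on one regular 3D grid (default
40×40×60 voxels, spacing dx = 1, voxel centres at (i+0.5)dx; z is the
dome axis).

**Mechanics (phase field).** The tissue is the region φ > 0 of an order
parameter φ with free energy

    F = ∫ ( Φ_SC² − ½ ϱ_φ |∇φ|² − ½ ϱ_u |∇u|² ) dV
    Φ_SC = −φ + φ³ − ϵ²∇²φ − ϵ β u² (φ² − 1)

(signs as stated; the negative tension terms mean monotone decay of F is
not guaranteed and is nowhere asserted). φ evolves conservatively,

    ∂φ/∂t = D_φ ∇²(δF/δφ) + m u² + κ m G + s_φ,

with mass addition m u², a Gaussian tip-growth source G and constant
primordium sources s_φ. The morphogen u is transported by the stress
tensor derived from the same energy density,

    ∂u/∂t = γ ∇·(σ ∇ δF/δu) + G + s_u ,

using the symmetrized σ as mobility (a diffusion mobility must be
symmetric for a well-posed flux; the raw tensor remains available as a
diagnostic). The closed forms of δF/δφ, δF/δu and σ_αβ implemented here
are the standard variational results for this energy; on the grid they
are the exact gradients of the discrete F (see *Discretisation*).

**Chemistry (BVAM).** (u, v) react and diffuse with kinetics
η(u + a v − c u v − u v²) and η(b v + h u + c u v + u v²), defaults
a = 1.1123, b = −1.0122, h = −1, D = 0.516, c ∈ [0, 0.57]. η has no
default and must be supplied: it encodes the domain size and selects the
Turing wavelength, hence the organ count around the dome. The linear
stability machinery (dispersion relation, unstable band, fastest
wavenumber, spherical-harmonic degree on a sphere) is closed-form for
the 2×2 Jacobian; the band is found by dense scan (2000 points over
[0, 4·k² scale]) plus Brent bisection to 1e-8.

## Two-time-scale scheduler

Shape change is 5000× slower than the chemistry (dt_chem = 5·10⁻²,
dt_mech = 10⁻⁵). Each outer cycle T runs `n_chem` chemical Euler steps
(a Turing "pulse") then `n_mech` mechanical Euler steps, refreshing σ
every `stress_every` mechanical steps (σ varies on the slow scale). All
stencils are second-order finite differences; time stepping is explicit
Euler throughout.

**Chemical boundary condition.** The pulse is solved on the tissue
interior: finite-volume diffusion with faces closed where either side
has φ ≤ 0, which is the discrete zero-flux condition on the moving
surface φ = 0, and kinetics applied only inside. The initial (u, v) is a
seeded uniform perturbation in [−0.1, 0.1] per voxel about the (0,0)
steady state, masked to the interior. (Solving the chemistry over the
whole box instead makes the surface sample an unadapted 3D spot lattice;
no whorl ring ever forms, and the spherical-harmonic mode-selection
argument — which presupposes the chemistry feels the domain boundary —
no longer applies. The unmasked solver remains available through
`bvam_step` without a mask.)

## Discretisation choices

* **Laplacian**: compact 7-point stencil, homogeneous-Neumann closure by
  mirror ghosts on the box faces. Its grid sum telescopes to zero, so
  Cahn–Hilliard updates conserve ∫φ to roundoff. Fourth- and sixth-order
  terms (∇² of variational derivatives) are nested applications of the
  same stencil.
* **Anisotropic transport** ∇·(σ∇μ): finite-volume face fluxes — normal
  derivative as a two-point difference on the face, tangential
  derivatives and tensor entries averaged onto the face, boundary faces
  carrying zero flux. This makes the operator reduce *exactly* to the
  7-point Laplacian for σ = I and conserve ∫u for arbitrary σ.
* **Discrete energy**: the |∇·|² tension terms use face (forward)
  differences, which are the exact discrete adjoint of the compact
  Laplacian. Consequence: the implemented closed-form variational
  derivatives are the exact gradients of the discrete F, and the
  numerical-perturbation oracle in the tests agrees to roundoff rather
  than to truncation order.
* **Curvature**: outward normal n = −∇φ/|∇φ| (φ > 0 inside), curvature
  tensor Q = (I − nn)·∇n, mean curvature H = ½ tr Q — so a sphere of
  radius R containing the tissue gives H = +1/R. Curvature is defined
  only on the interface band |φ| < 0.9 (masked elsewhere): outside the
  band |∇φ| degenerates and the normal is meaningless.
* **Hot loops**: the chemical step and the mechanical sub-step are fused
  numba kernels (fastmath disabled for reproducibility); the public
  numpy operators are the reference path, and a test pins kernel ==
  numpy to 1e-12. Trajectories are bit-reproducible from (config, seed).

## Geometry, growth and sources

The initial φ is tanh(d/√2ϵ) of the signed distance to a cylinder of
radius R = 10 (height H_z = 6) capped by a hemisphere; interface width
ϵ = 1 grid spacing (ϵ is not a published value; one voxel is the
narrowest resolvable interface and it is exposed in the config). The
tip-growth Gaussian G is isotropic with standard deviation `g_width`
(default R/2), centred on the axis at height summit−R so its distance
to the apex stays constant as the dome grows. Its amplitude rises
linearly with summit displacement, `tip_gain·(summit_z − summit_z(0) + 1)`.
The gain is the one constant in the model with no published value; the
default 0.2 was chosen so that the explicit scheme remains inside its
stability region over the simulated horizon — larger gains over-drive
φ > 1 on the axis, inflate the stress and eventually blow up the
transport step — while still producing monotone summit rise. Primordium
sources are constants s_φ, s_u inside balls of radius r_p = 2dx around
each fixed site; overlapping balls take the pointwise max so sources do
not double-add. A run that does diverge can either raise (default) or
truncate to the last finite cycle (`on_divergence = "truncate"`), which
is how sweeps and the acceptance runs survive late-time blow-ups.

## Detection and classification (artifact definitions)

The published analysis is visual; the rules here make it assertable.

* Surface: marching-cubes triangulation of φ = 0; per-vertex u and H by
  trilinear sampling.
* Threshold: mean + 2·SD of surface u, with an absolute floor 0.2 —
  above the seeded noise (≤ 0.1), well below the saturated pattern
  amplitude (≈ 1).
* Gate: detection starts only when the chemical pattern is stationary
  (relative change of interior std below 5% per cycle; exponential
  growth changes it by ≳ 10% per cycle). Candidates on a still-growing
  pulse drift and would fix at transient positions.
* Sites: connected over-threshold vertex clusters reduced to u-weighted
  centroids; fragments closer than `merge_radius` = 3 are merged (one
  spot can surface as several mesh clusters); clusters within `g_width`
  of the apex are excluded (organs never form at the summit).
* Fixation: a candidate persisting τ = 5 consecutive cycles within 3
  grid units becomes a permanent record; births within 25 cycles of a
  generation's first birth share that generation (plastochron index).
* Fold symmetry: record azimuths are collapsed into organ groups
  (circular single-linkage with a 5-grid-unit arc threshold at radius R
  — how one counts organs around the axis on a specimen, independent of
  their height scatter); uniform angular gaps give fold = group count
  when the sites are phase-coherent at that mode, otherwise the dominant
  angular Fourier mode over m = 1..min(12, n) (ties to the lower mode).
* Pattern call: ribbed if final-surface clusters are meridionally
  elongated stripes (median aspect ≥ 2 and median meridional span ≥ 5);
  whorled if the first generation is born near-simultaneously and is
  phase-coherent; spiral if births are staggered with a consistent
  azimuthal offset (circular std < 0.5 rad); otherwise aberrant.

## Desk-scale problem sizes

The default grid is the published 40×40×60. The package's desk-scale
schedule — used by the test suite, the examples and the acceptance
script — is n_chem = 400, n_mech = 500, stress refresh every 50
mechanical steps, horizon 110 cycles, stopping once the first generation
is fixed (~1–2.5 minutes per run on one core). With it the coupled model
robustly reproduces the 2-fold whorl (η = 0.2014) and the 5-fold whorl
(η = 0.8437, c = 0.33); intermediate η values select their fold
seed-dependently, typically one below the sphere-surface prediction (see
*Known limitations*). The two-time-scale structure is unchanged; only
the counts per cycle and the horizon are reduced relative to long
multi-plastochron runs (`examples/long_horizon_whorls.py`).

## Known limitations

* With the chemistry solved through the dome interior, the winning 3D
  bulk mode often carries one azimuthal fold less than the sphere-surface
  mode the η values map to (interior modes spend structure radially).
  Surface confinement of the pattern by stress-directed transport — which
  selects the surface fold — needs longer mechanical horizons than the
  desk schedule provides, so mid-range η folds are seed-dependent and
  biased one fold low at desk scale.
* The first Turing pulse deposits accumulation sites at more than one
  height (base ring and flank ring); the azimuthal-group fold absorbs
  this, but whorl *heights* are less localised than in long runs where
  the stress-directed transport has more time to act.
* For some seeds the mechanics suppresses a slow-growing pulse below the
  detection floor before it ever fixes; such runs report no pattern
  rather than a spurious one.
* At desk scale the stripe (c = 0) regimes are underdeveloped: the rib
  pattern needs a tall grown dome, so short runs read 3–4 azimuthal
  regions rather than the eventual 6, and the spiral case fixes its
  first ring one fold below its long-horizon symmetry.
* Sustained tip growth slowly pushes φ above 1 on the axis; the stress
  magnitude grows with it and the explicit transport step eventually
  diverges (hundreds of cycles at the desk schedule). Long-horizon runs
  therefore use `on_divergence = "truncate"`.
* Energy decay is not monotone and is not asserted (the printed tension
  terms enter with negative sign).
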