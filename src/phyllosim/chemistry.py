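"""BVAM reaction-diffusion system and its Turing linear-stability tools.

The morphogen pair (u, v) obeys, in non-dimensional form,

    du/dt = D lap(u) + eta (u + a v - c u v - u v^2)
    dv/dt =   lap(v) + eta (b v + h u + c u v + u v^2)

with (0, 0) the homogeneous steady state (the kinetics are a third-order
expansion about a conserved fixed point).  ``eta`` is a scaling parameter
that plays the role of domain size: on a sphere of radius r it selects the
spherical-harmonic degree l whose eigenvalue l(l+1)/r^2 sits nearest the
fastest-growing wavenumber, which is how the whorl symmetry of the coupled
simulation is steered.  ``c`` tilts the quadratic/cubic balance: c near the
top of its admissible range [0, 0.57] gives spots, c = 0 gives stripes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .calculus import laplacian_raw
from .grid import GridSpec, ScalarField3D

__all__ = [
    "BVAMParams",
    "bvam_reaction",
    "bvam_step",
    "seed_perturbation",
    "dispersion_relation",
    "turing_band",
    "predict_sphere_mode",
    "FieldDivergenceError",
    "NoTuringPatternError",
]


class FieldDivergenceError(RuntimeError):
    """A time step produced non-finite values in a named field."""


class NoTuringPatternError(RuntimeError):
    """The parameter set has no unstable wavenumber band."""


@dataclass(frozen=True)
class BVAMParams:
    """Kinetic coefficients of the BVAM system (all dimensionless).

    ``eta`` has no canonical default -- it encodes the domain size and is
    the main experimental dial -- so it must always be supplied.
    """

    eta: float
    a: float = 1.1123
    b: float = -1.0122
    c: float = 0.57
    h: float = -1.0
    D: float = 0.516

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusivity ratio D must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


def bvam_reaction(u, v, p: BVAMParams):
    """Pointwise kinetics (du, dv); accepts scalars or arrays."""
    uv = u * v
    uvv = uv * v
    du = p.eta * (u + p.a * v - p.c * uv - uvv)
    dv = p.eta * (p.b * v + p.h * u + p.c * uv + uvv)
    return du, dv


def bvam_step(
    u: ScalarField3D,
    v: ScalarField3D,
    p: BVAMParams,
    dt: float | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ScalarField3D, ScalarField3D]:
    """One explicit Euler step of the reaction-diffusion system.

    With ``mask`` (1 inside / 0 outside) the solve is confined to the
    masked region with zero flux through its boundary, the condition the
    coupled simulation imposes on the tissue surface; without it the whole
    box reacts and diffuses under the box-face Neumann closure.
    """
    grid = u.grid
    if dt is None:
        dt = grid.dt_chem
    fu, fv = bvam_reaction(u.values, v.values, p)
    if mask is None:
        lu = laplacian_raw(u.values, grid.dx)
        lv = laplacian_raw(v.values, grid.dx)
    else:
        from .calculus import masked_laplacian_raw

        mask = np.asarray(mask, dtype=float)
        lu = masked_laplacian_raw(u.values, mask, grid.dx)
        lv = masked_laplacian_raw(v.values, mask, grid.dx)
        fu = fu * mask
        fv = fv * mask
    un = u.values + dt * (p.D * lu + fu)
    vn = v.values + dt * (lv + fv)
    for name, arr in (("u", un), ("v", vn)):
        if not np.all(np.isfinite(arr)):
            raise FieldDivergenceError(f"field '{name}' diverged during a chemical step")
    return ScalarField3D(un, grid), ScalarField3D(vn, grid)


def seed_perturbation(
    grid: GridSpec, seed: int, amplitude: float = 0.1
) -> tuple[ScalarField3D, ScalarField3D]:
    """Seeded uniform random perturbation of (u, v) about (0, 0).

    The run starts from iid noise in [-amplitude, amplitude] per voxel, the
    standard way of letting the Turing instability pick its own pattern.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(-amplitude, amplitude, grid.shape)
    v = rng.uniform(-amplitude, amplitude, grid.shape)
    return ScalarField3D(u, grid), ScalarField3D(v, grid)


def _jacobian(p: BVAMParams, k2: float) -> np.ndarray:
    return np.array(
        [
            [p.eta - p.D * k2, p.eta * p.a],
            [p.eta * p.h, p.eta * p.b - k2],
        ]
    )


def dispersion_relation(p: BVAMParams, k2: float) -> float:
    """Max real part of the growth-rate eigenvalues at squared wavenumber k2.

    Closed form for the 2x2 linearisation about (0,0); positive values mark
    Turing-unstable wavenumbers.
    """
    if k2 < 0:
        raise ValueError("k2 must be non-negative")
    J = _jacobian(p, k2)
    tr = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = 0.25 * tr * tr - det
    if disc >= 0:
        return 0.5 * tr + np.sqrt(disc)
    return 0.5 * tr


def turing_band(
    p: BVAMParams, n_scan: int = 2000, tol: float = 1e-8
) -> tuple[float, float] | None:
    """Contiguous interval of k^2 with positive growth rate, or ``None``.

    Dense scan over ``[0, 4 * k2_peak_estimate]`` followed by bisection of
    the endpoints.  If the homogeneous state itself is unstable
    (dispersion > 0 at k2 = 0) the band is still returned, but callers can
    detect the situation from the lower endpoint being 0.
    """
    # estimate of the band scale from the determinant minimum:
    # det(k2) = D k^4 - eta (1 + D b) k2 + eta^2 (b - a h)
    k2_scale = max(p.eta * abs(1.0 + p.D * p.b) / p.D, p.eta)
    k2_hi_scan = 4.0 * k2_scale
    k2s = np.linspace(0.0, k2_hi_scan, n_scan)
    lam = np.array([dispersion_relation(p, k2) for k2 in k2s])
    pos = lam > 0
    if not pos.any():
        return None
    idx = np.flatnonzero(pos)
    lo_i, hi_i = idx[0], idx[-1]
    f = lambda k2: dispersion_relation(p, k2)  # noqa: E731
    if lo_i == 0:
        k2_lo = 0.0
    else:
        k2_lo = brentq(f, k2s[lo_i - 1], k2s[lo_i], xtol=tol)
    if hi_i == len(k2s) - 1:
        k2_hi = k2s[-1]
    else:
        k2_hi = brentq(f, k2s[hi_i], k2s[hi_i + 1], xtol=tol)
    return (float(k2_lo), float(k2_hi))


def fastest_wavenumber(p: BVAMParams) -> float:
    """Squared wavenumber maximising the dispersion relation over the band."""
    band = turing_band(p)
    if band is None:
        raise NoTuringPatternError("no unstable wavenumber band for these parameters")
    res = minimize_scalar(
        lambda k2: -dispersion_relation(p, k2), bounds=band, method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def predict_sphere_mode(p: BVAMParams, radius: float, l_max: int = 30) -> int:
    """Spherical-harmonic degree selected by the instability on a sphere.

    The degree-l eigenvalue of the Laplace-Beltrami operator on a sphere of
    the given radius is l(l+1)/radius^2; the predicted pattern symmetry is
    the degree whose eigenvalue lies closest to the fastest-growing k^2.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    k2_star = fastest_wavenumber(p)
    ls = np.arange(1, l_max + 1)
    ev = ls * (ls + 1) / radius**2
    return int(ls[np.argmin(np.abs(ev - k2_star))])
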