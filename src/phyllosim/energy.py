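"""Spontaneous-curvature free energy and its variational derivatives.

The tissue surface is the zero level set of a phase field phi (+1 inside,
-1 outside).  Its free energy is a Ginzburg-Landau square with a
morphogen-dependent spontaneous-curvature term and surface-tension costs:

    Phi[phi]    = -phi + phi^3 - eps^2 lap(phi)
    C0[u]       = beta u^2
    Phi_SC      = Phi[phi] - eps C0[u] (phi^2 - 1)
    F           = Integral( Phi_SC^2 - 1/2 rho_phi |grad phi|^2
                                     - 1/2 rho_u  |grad u|^2 ) dV

The ``(phi^2 - 1)`` factor acts as a delta function on the interface, so
the morphogen only bends the surface, never the bulk.  The variational
derivatives below are the printed closed forms; on the discrete grid they
are the *exact* gradients of the discrete F because the tension terms are
discretised with face differences (the adjoint of the compact Laplacian).

Signs follow the printed energy: the tension terms enter with a minus, so
monotone decay of F is not guaranteed and is not asserted anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calculus import laplacian_raw
from .grid import GridSpec, ScalarField3D

__all__ = [
    "MechParams",
    "EnergyFields",
    "phi_functional",
    "spontaneous_curvature",
    "phi_sc",
    "free_energy",
    "dF_dphi",
    "dF_du",
]


@dataclass(frozen=True)
class MechParams:
    """Parameters of the mechanical (phase-field) model.

    eps       : interface width (grid units; the tanh profile scale)
    beta      : strength of the morphogen's influence on spontaneous curvature
    gamma     : stress-transport coupling (mobility prefactor of u)
    m         : mass-addition rate (growth per unit u^2)
    kappa     : gain of the tip-growth Gaussian in the phi equation
    D_phi     : phase-field mobility
    rho_phi   : surface-tension coefficient of phi (stiff epidermis)
    rho_u     : surface-tension coefficient of u (much softer)
    R         : dome radius of the initial cylinder-plus-hemisphere domain
    Hz        : initial cylinder height
    g_width   : standard deviation of the tip-growth Gaussian (default R/2)
    s_phi,s_u : primordium source strengths (constant inside source balls)
    r_p       : primordium source-ball radius (grid units)
    tip_gain  : amplitude gain of the tip Gaussian per unit summit rise
    """

    eps: float = 1.0
    beta: float = 0.5
    gamma: float = 0.2
    m: float = 15.0
    kappa: float = 2.0
    D_phi: float = 1.0
    rho_phi: float = 2.5
    rho_u: float = 0.5
    R: float = 10.0
    Hz: float = 6.0
    g_width: float = 5.0
    s_phi: float = 0.5
    s_u: float = 0.5
    r_p: float = 2.0
    tip_gain: float = 0.2

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("interface width eps must be positive")
        if self.D_phi <= 0:
            raise ValueError("phase-field mobility D_phi must be positive")
        if not (self.rho_phi >= self.rho_u >= 0):
            raise ValueError("need rho_phi >= rho_u >= 0")


@dataclass
class EnergyFields:
    """Free energy and all densities derived from one (phi, u) pair."""

    Phi: ScalarField3D
    PhiSC: ScalarField3D
    density: ScalarField3D
    F: float
    mu_phi: ScalarField3D
    mu_u: ScalarField3D


# ---------------------------------------------------------------------------
# raw-array forms
# ---------------------------------------------------------------------------

def phi_functional_raw(phi: np.ndarray, eps: float, dx: float) -> np.ndarray:
    return -phi + phi**3 - eps * eps * laplacian_raw(phi, dx)


def phi_sc_raw(phi: np.ndarray, u: np.ndarray, p: MechParams, dx: float) -> np.ndarray:
    Phi = phi_functional_raw(phi, p.eps, dx)
    return Phi - p.eps * (p.beta * u * u) * (phi * phi - 1.0)


def face_grad_sq(f: np.ndarray, dx: float) -> np.ndarray:
    """|grad f|^2 from face (forward) differences, assigned to the lower cell.

    Boundary faces carry zero difference (the zero-flux closure), so the sum
    of this density is the discrete Dirichlet energy whose exact gradient is
    the compact 7-point Laplacian.
    """
    out = np.zeros_like(f)
    inv2 = 1.0 / (dx * dx)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        d2 = (f[tuple(hi)] - f[tuple(lo)]) ** 2 * inv2
        out[tuple(lo)] += d2
    return out


def energy_density_raw(phi: np.ndarray, u: np.ndarray, p: MechParams, dx: float) -> np.ndarray:
    psc = phi_sc_raw(phi, u, p, dx)
    return (
        psc * psc
        - 0.5 * p.rho_phi * face_grad_sq(phi, dx)
        - 0.5 * p.rho_u * face_grad_sq(u, dx)
    )


def dF_dphi_raw(phi: np.ndarray, u: np.ndarray, p: MechParams, dx: float) -> np.ndarray:
    psc = phi_sc_raw(phi, u, p, dx)
    bulk = 3.0 * phi * phi - 1.0 - 2.0 * phi * p.eps * p.beta * u * u
    return 2.0 * (bulk * psc - p.eps * p.eps * laplacian_raw(psc, dx)) + p.rho_phi * laplacian_raw(phi, dx)


def dF_du_raw(phi: np.ndarray, u: np.ndarray, p: MechParams, dx: float) -> np.ndarray:
    psc = phi_sc_raw(phi, u, p, dx)
    return -4.0 * p.eps * (phi * phi - 1.0) * p.beta * u * psc + p.rho_u * laplacian_raw(u, dx)


# ---------------------------------------------------------------------------
# field-level API
# ---------------------------------------------------------------------------

def phi_functional(phi: ScalarField3D, p: MechParams) -> ScalarField3D:
    """Phi[phi] = -phi + phi^3 - eps^2 lap(phi); zero in both bulk phases."""
    return ScalarField3D(phi_functional_raw(phi.values, p.eps, phi.grid.dx), phi.grid)


def spontaneous_curvature(u: ScalarField3D, p: MechParams) -> ScalarField3D:
    """C0 = beta u^2: the morphogen-set preferred curvature."""
    return ScalarField3D(p.beta * u.values**2, u.grid)


def phi_sc(phi: ScalarField3D, u: ScalarField3D, p: MechParams) -> ScalarField3D:
    """Phi_SC = Phi[phi] - eps C0[u] (phi^2 - 1)."""
    return ScalarField3D(phi_sc_raw(phi.values, u.values, p, phi.grid.dx), phi.grid)


def free_energy(phi: ScalarField3D, u: ScalarField3D, p: MechParams) -> EnergyFields:
    """Total free energy and every density derived from (phi, u)."""
    grid = phi.grid
    dx = grid.dx
    Phi = phi_functional_raw(phi.values, p.eps, dx)
    psc = phi_sc_raw(phi.values, u.values, p, dx)
    dens = (
        psc * psc
        - 0.5 * p.rho_phi * face_grad_sq(phi.values, dx)
        - 0.5 * p.rho_u * face_grad_sq(u.values, dx)
    )
    return EnergyFields(
        Phi=ScalarField3D(Phi, grid),
        PhiSC=ScalarField3D(psc, grid),
        density=ScalarField3D(dens, grid),
        F=float(dens.sum() * grid.voxel_volume),
        mu_phi=ScalarField3D(dF_dphi_raw(phi.values, u.values, p, dx), grid),
        mu_u=ScalarField3D(dF_du_raw(phi.values, u.values, p, dx), grid),
    )


def dF_dphi(phi: ScalarField3D, u: ScalarField3D, p: MechParams) -> ScalarField3D:
    """delta F / delta phi, the chemical potential driving surface motion."""
    return ScalarField3D(dF_dphi_raw(phi.values, u.values, p, phi.grid.dx), phi.grid)


def dF_du(phi: ScalarField3D, u: ScalarField3D, p: MechParams) -> ScalarField3D:
    """delta F / delta u, the potential whose stress-directed flux moves u."""
    return ScalarField3D(dF_du_raw(phi.values, u.values, p, phi.grid.dx), phi.grid)
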