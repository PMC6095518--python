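"""Stress and curvature tensors of the phase field.

The stress tensor is derived from the free-energy density L of the
phase-field theory,

    sigma_ab = (L - phi dL/dphi) delta_ab
               - dL/d(grad_b phi) grad_a phi
               + grad_b[ dL/d(lap phi) ] grad_a phi
               - dL/d(lap phi) grad_a grad_b phi,

whose first term is hydrostatic pressure, whose middle terms carry the
surface tension of phi, and whose third term contains the curvature tensor
of the interface.  The symmetrized sigma is what the transport equation
uses as the morphogen's diffusion mobility (a mobility must be symmetric
for a well-posed flux); the raw tensor stays available for diagnostics.

The curvature tensor is the projected gradient of the outward unit normal
n = -grad(phi)/|grad(phi)| (phi > 0 inside the tissue):

    Q_ab = (delta_ag - n_a n_g) grad_g n_b,      H = 1/2 tr(Q),

so a sphere of radius R enclosing phi > 0 has H = +1/R.  Curvature is only
defined on the interface band |phi| < 0.9 where the normal is resolvable.
"""

from __future__ import annotations

import numpy as np

from .calculus import gradient_raw
from .energy import MechParams
from .grid import ScalarField3D, TensorField3D, VectorField3D

__all__ = [
    "stress_tensor",
    "curvature_tensor",
    "principal_stress",
    "interface_band",
]

BAND_LIMIT = 0.9


def stress_tensor_raw(phi: np.ndarray, u: np.ndarray, p: MechParams, dx: float) -> np.ndarray:
    # inlined psc / L / mu sharing the Laplacians (this runs in the hot loop)
    from .calculus import laplacian_raw
    from .energy import face_grad_sq

    e2 = p.eps * p.eps
    lap_phi = laplacian_raw(phi, dx)
    u2 = u * u
    psc = -phi + phi**3 - e2 * lap_phi - p.eps * p.beta * u2 * (phi * phi - 1.0)
    lap_psc = laplacian_raw(psc, dx)
    bulk = 3.0 * phi * phi - 1.0 - 2.0 * phi * p.eps * p.beta * u2
    mu = 2.0 * (bulk * psc - e2 * lap_psc) + p.rho_phi * lap_phi
    L = (psc * psc - 0.5 * p.rho_phi * face_grad_sq(phi, dx)
         - 0.5 * p.rho_u * face_grad_sq(u, dx))
    gphi = gradient_raw(phi, dx)
    gpsc = gradient_raw(psc, dx)

    sigma = np.zeros(phi.shape + (3, 3))
    iso = L - phi * mu
    for a in range(3):
        sigma[..., a, a] = iso

    # Hessian of phi by nested central differences
    hess = np.empty(phi.shape + (3, 3))
    for a in range(3):
        ga = gradient_raw(gphi[..., a], dx)
        for b in range(3):
            hess[..., a, b] = ga[..., b]
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))

    for a in range(3):
        for b in range(3):
            sigma[..., a, b] += (
                p.rho_phi * gphi[..., b] * gphi[..., a]
                - 2.0 * e2 * gpsc[..., b] * gphi[..., a]
                + 2.0 * e2 * psc * hess[..., a, b]
            )
    return sigma


def stress_tensor(phi: ScalarField3D, u: ScalarField3D, p: MechParams) -> TensorField3D:
    """Stress tensor sigma_ab of the coupled (phi, u) energy density."""
    sigma = stress_tensor_raw(phi.values, u.values, p, phi.grid.dx)
    if not np.all(np.isfinite(sigma)):
        bad = np.argwhere(~np.isfinite(sigma).all(axis=(-1, -2)))[0]
        raise FloatingPointError(f"non-finite stress at voxel {tuple(bad)}")
    return TensorField3D(sigma, phi.grid)


def interface_band(phi: ScalarField3D, limit: float = BAND_LIMIT) -> np.ndarray:
    """Boolean mask of the interface band |phi| < limit."""
    return np.abs(phi.values) < limit


def curvature_tensor(
    phi: ScalarField3D, p: MechParams | None = None, grad_floor: float = 1e-8
) -> tuple[TensorField3D, ScalarField3D, np.ndarray]:
    """Curvature tensor Q, mean curvature H and the band mask.

    Returns ``(Q, H, band)``.  Q and H are zero-filled outside the band
    ``|phi| < 0.9`` (and wherever the phase-field gradient degenerates);
    only voxels with ``band`` True carry defined curvature.
    """
    grid = phi.grid
    g = gradient_raw(phi.values, grid.dx)
    norm = np.sqrt((g**2).sum(axis=-1))
    safe = np.maximum(norm, grad_floor)
    n = -g / safe[..., None]  # outward normal (phi > 0 inside)

    dn = np.empty(grid.shape + (3, 3))  # dn[..., g_idx, b] = grad_g n_b
    for b in range(3):
        gb = gradient_raw(n[..., b], grid.dx)
        for gidx in range(3):
            dn[..., gidx, b] = gb[..., gidx]

    # Q_ab = (delta_ag - n_a n_g) grad_g n_b
    Q = dn - n[..., :, None] * np.einsum("...g,...gb->...b", n, dn)[..., None, :]
    H = 0.5 * np.trace(Q, axis1=-2, axis2=-1)

    band = interface_band(phi) & (norm > grad_floor)
    Q = np.where(band[..., None, None], Q, 0.0)
    H = np.where(band, H, 0.0)
    return TensorField3D(Q, grid), ScalarField3D(H, grid), band


def principal_stress(
    T: TensorField3D,
) -> tuple[list[VectorField3D], list[ScalarField3D]]:
    """Per-voxel eigendecomposition of the symmetrized tensor.

    Eigenvalues are sorted descending; each eigenvector's sign is fixed by
    making its largest-magnitude component positive.
    """
    sym = T.symmetrized().values
    w, v = np.linalg.eigh(sym)  # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]  # columns are eigenvectors
    # deterministic sign: flip so the largest-|component| is positive
    for i in range(3):
        vec = v[..., :, i]
        idx = np.argmax(np.abs(vec), axis=-1)
        sign = np.sign(np.take_along_axis(vec, idx[..., None], axis=-1))[..., 0]
        sign = np.where(sign == 0, 1.0, sign)
        v[..., :, i] = vec * sign[..., None]
    directions = [VectorField3D(np.ascontiguousarray(v[..., :, i]), T.grid) for i in range(3)]
    magnitudes = [ScalarField3D(np.ascontiguousarray(w[..., i]), T.grid) for i in range(3)]
    return directions, magnitudes
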