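"""Second-order finite-difference operators on the regular grid.

All PDE terms in the model are discretised here.  Boundary closure is
homogeneous Neumann (zero normal flux) on the six box faces, realised by
ghost-cell mirroring; the chemistry-to-mechanics couplings carry
``(phi^2 - 1)`` factors that vanish away from the tissue interface, so the
box faces only ever see bulk phase.

Two discrete structures matter for conservation:

* the 7-point Laplacian with mirrored ghosts telescopes to zero under the
  grid sum, so Cahn-Hilliard updates conserve the phase-field integral to
  roundoff;
* :func:`anisotropic_flux_divergence` is written in finite-volume form
  (fluxes on voxel faces, zero on boundary faces), so its grid sum is zero
  for *any* mobility tensor and the isotropic limit reduces exactly to
  :func:`laplacian`.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, ScalarField3D, TensorField3D, VectorField3D

__all__ = [
    "laplacian",
    "gradient",
    "divergence",
    "anisotropic_flux_divergence",
]

_MIN_EXTENT = 3  # stencil support


def _require_grid(grid: GridSpec) -> None:
    if min(grid.nx, grid.ny, grid.nz) < _MIN_EXTENT:
        raise ValueError("grid smaller than the stencil support")


# ---------------------------------------------------------------------------
# raw-array kernels (used internally and by the dynamics fast path)
# ---------------------------------------------------------------------------

def laplacian_raw(f: np.ndarray, dx: float, out: np.ndarray | None = None) -> np.ndarray:
    """Compact 7-point Laplacian with even (mirror) ghost closure."""
    g = np.pad(f, 1, mode="edge")
    if out is None:
        out = np.empty_like(f)
    np.add(g[2:, 1:-1, 1:-1], g[:-2, 1:-1, 1:-1], out=out)
    out += g[1:-1, 2:, 1:-1]
    out += g[1:-1, :-2, 1:-1]
    out += g[1:-1, 1:-1, 2:]
    out += g[1:-1, 1:-1, :-2]
    out -= 6.0 * f
    out /= dx * dx
    return out


def masked_laplacian_raw(f: np.ndarray, mask: np.ndarray, dx: float) -> np.ndarray:
    """Finite-volume Laplacian on the region ``mask == 1``.

    Faces with either side outside the region are closed (zero flux), the
    discrete Neumann condition on an irregular embedded boundary.  Returns
    zero outside the region.
    """
    out = np.zeros_like(f)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        open_face = mask[tuple(lo)] * mask[tuple(hi)]
        d = (f[tuple(hi)] - f[tuple(lo)]) * open_face
        out[tuple(lo)] += d
        out[tuple(hi)] -= d
    return out * mask / (dx * dx)


def gradient_raw(f: np.ndarray, dx: float) -> np.ndarray:
    """Central-difference gradient, even ghost closure (zero normal slope)."""
    g = np.pad(f, 1, mode="edge")
    inv = 0.5 / dx
    out = np.empty(f.shape + (3,))
    out[..., 0] = (g[2:, 1:-1, 1:-1] - g[:-2, 1:-1, 1:-1]) * inv
    out[..., 1] = (g[1:-1, 2:, 1:-1] - g[1:-1, :-2, 1:-1]) * inv
    out[..., 2] = (g[1:-1, 1:-1, 2:] - g[1:-1, 1:-1, :-2]) * inv
    return out


def divergence_raw(v: np.ndarray, dx: float) -> np.ndarray:
    """Central-difference divergence with odd (zero-flux) ghost closure.

    Each component is reflected antisymmetrically across its own boundary
    faces, which is the discrete statement that no flux leaves the box.
    """
    inv = 0.5 / dx
    out = np.zeros(v.shape[:-1])
    for axis in range(3):
        comp = v[..., axis]
        g = np.pad(comp, [(1, 1) if a == axis else (0, 0) for a in range(3)], mode="edge")
        # odd reflection: ghost = -edge value
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = 0
        sl_hi[axis] = -1
        g[tuple(sl_lo)] = -g[tuple(sl_lo)]
        g[tuple(sl_hi)] = -g[tuple(sl_hi)]
        up = [slice(None)] * 3
        dn = [slice(None)] * 3
        up[axis] = slice(2, None)
        dn[axis] = slice(None, -2)
        out += (g[tuple(up)] - g[tuple(dn)]) * inv
    return out


def _face_average(a: np.ndarray, axis: int) -> np.ndarray:
    """Average of neighbouring voxels onto interior faces along ``axis``."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    return 0.5 * (a[tuple(lo)] + a[tuple(hi)])


def anisotropic_flux_divergence_raw(T: np.ndarray, s: np.ndarray, dx: float) -> np.ndarray:
    """div(T grad s) in finite-volume (face-flux) form.

    ``T`` has shape ``(*grid, 3, 3)``.  Normal derivatives on a face are
    compact two-point differences; tangential derivatives and tensor entries
    are averaged onto the face.  Boundary faces carry zero flux, so the grid
    sum vanishes identically and ``T = I`` reproduces the 7-point Laplacian
    exactly.
    """
    if not np.all(np.isfinite(T)):
        raise ValueError("mobility tensor contains non-finite entries")
    grad_c = gradient_raw(s, dx)  # cell-centred, for tangential face terms
    out = np.zeros_like(s)
    for alpha in range(3):
        # flux component through faces normal to axis alpha
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[alpha] = slice(None, -1)
        hi[alpha] = slice(1, None)
        normal = (s[tuple(hi)] - s[tuple(lo)]) / dx
        flux = _face_average(T[..., alpha, alpha], alpha) * normal
        for beta in range(3):
            if beta == alpha:
                continue
            flux += _face_average(T[..., alpha, beta] * grad_c[..., beta], alpha)
        # divergence: (F_{i+1/2} - F_{i-1/2}) / dx with zero boundary faces
        acc = np.zeros_like(s)
        acc[tuple(lo)] += flux  # plus-side face of the lower cell
        acc[tuple(hi)] -= flux  # minus-side face of the upper cell
        out += acc / dx
    return out


# ---------------------------------------------------------------------------
# field-level API
# ---------------------------------------------------------------------------

def laplacian(f: ScalarField3D) -> ScalarField3D:
    """7-point Laplacian of a scalar field (exact for quadratics inside)."""
    _require_grid(f.grid)
    return ScalarField3D(laplacian_raw(f.values, f.grid.dx), f.grid)


def gradient(f: ScalarField3D) -> VectorField3D:
    """Component-wise central-difference gradient."""
    _require_grid(f.grid)
    return VectorField3D(gradient_raw(f.values, f.grid.dx), f.grid)


def divergence(v: VectorField3D) -> ScalarField3D:
    """Central-difference divergence with the zero-flux closure."""
    _require_grid(v.grid)
    return ScalarField3D(divergence_raw(v.values, v.grid.dx), v.grid)


def anisotropic_flux_divergence(T: TensorField3D, s: ScalarField3D) -> ScalarField3D:
    """div(T grad s): the stress-directed transport operator."""
    if T.grid.shape != s.grid.shape:
        raise ValueError("tensor and scalar live on different grids")
    _require_grid(s.grid)
    return ScalarField3D(
        anisotropic_flux_divergence_raw(T.values, s.values, s.grid.dx), s.grid
    )
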