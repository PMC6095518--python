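"""Analytic phase-field and surface fixtures.

Tanh profiles of known signed-distance functions (sphere, cylinder,
cylinder-plus-hemisphere dome, plane) and constructed surface morphogen
fields with a prescribed number of bumps.  These give every geometric
operation in the package an analytic oracle.
"""

from __future__ import annotations

import numpy as np

from .energy import MechParams
from .grid import GridSpec, ScalarField3D

__all__ = ["make_fixture", "tanh_profile", "signed_distance_dome"]


def tanh_profile(d: np.ndarray, eps: float) -> np.ndarray:
    """Equilibrium interface profile of a signed distance field d (>0 inside)."""
    return np.tanh(d / (np.sqrt(2.0) * eps))


def signed_distance_dome(
    grid: GridSpec, R: float, Hz: float
) -> np.ndarray:
    """Signed distance (positive inside) to a cylinder of radius R capped at
    height Hz by a hemisphere of the same radius, both centred on the box axis."""
    x, y, z = grid.meshgrid()
    cx, cy = grid.axis_xy
    r_xy = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    d_cyl = R - r_xy
    d_cap = R - np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - Hz) ** 2)
    return np.where(z <= Hz, d_cyl, d_cap)


def make_fixture(kind: str, grid: GridSpec | None = None, **params):
    """Build an analytic fixture.

    kinds
    -----
    ``sphere``    : tanh sphere; params ``radius`` (req), ``center``, ``eps``.
    ``cylinder``  : tanh cylinder about the z axis; params ``radius``, ``eps``.
    ``dome``      : cylinder-plus-hemisphere initial domain; ``R``, ``Hz``, ``eps``.
    ``plane``     : horizontal interface, phi>0 below; params ``z0``, ``eps``.
    ``bumps``     : dome SurfaceMesh whose per-vertex u carries ``k`` equally
                    spaced Gaussian bumps on the ring at ``height``; params
                    ``k`` (req), ``height``, ``bump_width``, ``amplitude``,
                    ``phase``.
    """
    if grid is None:
        grid = GridSpec()
    eps = params.get("eps", 1.0)
    x, y, z = grid.meshgrid()
    cx, cy = grid.axis_xy

    if kind == "sphere":
        radius = params["radius"]
        center = params.get(
            "center", (cx, cy, 0.5 * grid.nz * grid.dx)
        )
        d = radius - np.sqrt(
            (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        )
        return ScalarField3D(tanh_profile(d, eps), grid)

    if kind == "cylinder":
        radius = params["radius"]
        d = radius - np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        return ScalarField3D(tanh_profile(d, eps), grid)

    if kind == "dome":
        R = params.get("R", 10.0)
        Hz = params.get("Hz", 6.0)
        d = signed_distance_dome(grid, R, Hz)
        return ScalarField3D(tanh_profile(d, eps), grid)

    if kind == "plane":
        z0 = params.get("z0", 0.5 * grid.nz * grid.dx)
        return ScalarField3D(tanh_profile(z0 - z, eps), grid)

    if kind == "bumps":
        from .analysis import extract_isosurface, sample_on_mesh

        k = int(params["k"])
        R = params.get("R", 10.0)
        Hz = params.get("Hz", 6.0)
        height = params.get("height", Hz)
        width = params.get("bump_width", 2.0)
        amplitude = params.get("amplitude", 1.0)
        phase = params.get("phase", 0.0)
        phi = ScalarField3D(tanh_profile(signed_distance_dome(grid, R, Hz), eps), grid)
        mesh = extract_isosurface(phi)
        verts = mesh.vertices
        az = np.arctan2(verts[:, 1] - cy, verts[:, 0] - cx)
        u = np.zeros(len(verts))
        # bump centres sit on the dome surface at the requested height
        r_ring = R if height <= Hz else float(np.sqrt(max(R**2 - (height - Hz) ** 2, 0.0)))
        for i in range(k):
            theta = phase + 2.0 * np.pi * i / k
            bx = cx + r_ring * np.cos(theta)
            by = cy + r_ring * np.sin(theta)
            d2 = ((verts[:, 0] - bx) ** 2 + (verts[:, 1] - by) ** 2
                  + (verts[:, 2] - height) ** 2)
            u += amplitude * np.exp(-d2 / (2.0 * width**2))
        mesh.u = u
        mesh.azimuth = np.mod(az, 2.0 * np.pi)
        mesh.height = verts[:, 2].copy()
        return mesh

    raise ValueError(f"unknown fixture kind: {kind!r}")


def initialize_domain(grid: GridSpec, p: MechParams) -> ScalarField3D:
    """Initial phase field: the tanh dome of radius R capped at height Hz.

    Rejects domes that do not fit the grid with 5 voxels of clearance.
    """
    cx, cy = grid.axis_xy
    clearance = 5 * grid.dx
    if (cx - p.R < clearance or cy - p.R < clearance
            or p.Hz + p.R > grid.nz * grid.dx - clearance):
        raise ValueError("dome does not fit in the grid with 5-voxel clearance")
    return ScalarField3D(
        tanh_profile(signed_distance_dome(grid, p.R, p.Hz), p.eps), grid
    )
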