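"""Regular-grid containers for the simulator.

Every PDE field lives on one uniform Cartesian grid of ``nx x ny x nz``
voxels with spacing ``dx``.  Voxel ``(i, j, k)`` is centred at
``((i + 0.5) dx, (j + 0.5) dx, (k + 0.5) dx)`` with ``z`` (index ``k``)
the dome axis.  Two time steps are carried on the grid spec because the
model is integrated on two scales: a fast chemical step ``dt_chem`` and a
slow mechanical step ``dt_mech`` (their ratio is the model's 5000-fold
separation between morphogen dynamics and shape change).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "ScalarField3D",
    "VectorField3D",
    "TensorField3D",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry and time-step bundle of the simulation grid."""

    nx: int = 40
    ny: int = 40
    nz: int = 60
    dx: float = 1.0
    dt_chem: float = 5e-2
    dt_mech: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 8:
            raise ValueError("grid needs at least 8 voxels per axis")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.dt_chem <= 0 or self.dt_mech <= 0:
            raise ValueError("time steps must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_volume(self) -> float:
        return self.dx**3

    def axis_centers(self, axis: int) -> np.ndarray:
        """Coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.dx

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate arrays (each of shape ``self.shape``)."""
        return np.meshgrid(
            self.axis_centers(0),
            self.axis_centers(1),
            self.axis_centers(2),
            indexing="ij",
        )

    @property
    def axis_xy(self) -> tuple[float, float]:
        """(x, y) of the dome axis: the box centre."""
        return (0.5 * self.nx * self.dx, 0.5 * self.ny * self.dx)


def _check_values(values: np.ndarray, grid: GridSpec, trailing: tuple[int, ...]) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape + trailing:
        raise ValueError(
            f"field shape {values.shape} does not match grid {grid.shape + trailing}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("field contains non-finite values")
    return values


@dataclass
class ScalarField3D:
    """A real scalar per voxel (phi, u, v or any derived density)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, self.grid, ())

    @classmethod
    def full(cls, grid: GridSpec, value: float = 0.0) -> "ScalarField3D":
        return cls(np.full(grid.shape, float(value)), grid)

    @classmethod
    def from_function(cls, grid: GridSpec, fn) -> "ScalarField3D":
        x, y, z = grid.meshgrid()
        return cls(np.asarray(fn(x, y, z), dtype=float), grid)

    def integral(self) -> float:
        """Grid sum times voxel volume."""
        return float(self.values.sum() * self.grid.voxel_volume)

    def copy(self) -> "ScalarField3D":
        return ScalarField3D(self.values.copy(), self.grid)


@dataclass
class VectorField3D:
    """Three real components per voxel, stored as ``(*grid.shape, 3)``."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, self.grid, (3,))

    @classmethod
    def zeros(cls, grid: GridSpec) -> "VectorField3D":
        return cls(np.zeros(grid.shape + (3,)), grid)

    def component(self, axis: int) -> ScalarField3D:
        return ScalarField3D(self.values[..., axis].copy(), self.grid)


@dataclass
class TensorField3D:
    """A 3x3 real tensor per voxel, stored as ``(*grid.shape, 3, 3)``.

    Houses the stress tensor sigma, the curvature tensor Q, and the
    stress-proportional diffusion mobility gamma*sigma.
    """

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, self.grid, (3, 3))

    @classmethod
    def zeros(cls, grid: GridSpec) -> "TensorField3D":
        return cls(np.zeros(grid.shape + (3, 3)), grid)

    @classmethod
    def isotropic(cls, grid: GridSpec, c: float = 1.0) -> "TensorField3D":
        values = np.zeros(grid.shape + (3, 3))
        for a in range(3):
            values[..., a, a] = c
        return cls(values, grid)

    def symmetrized(self) -> "TensorField3D":
        return TensorField3D(0.5 * (self.values + np.swapaxes(self.values, -1, -2)), self.grid)

    def asymmetry_norm(self) -> float:
        """Frobenius norm of the antisymmetric part (diagnostic)."""
        anti = 0.5 * (self.values - np.swapaxes(self.values, -1, -2))
        return float(np.sqrt((anti**2).sum()))
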