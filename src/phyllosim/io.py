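"""Snapshot persistence and export.

Snapshots are HDF5 (phi, u, v, primordium table, cycle counter, seed);
volumetric fields export as legacy-ASCII VTK structured points, meshes as
legacy-ASCII VTK polydata (with per-vertex H and u) or PLY via trimesh,
and tables as CSV with a fixed, documented column schema.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .analysis import PrimordiumRecord, SurfaceMesh
from .dynamics import SimulationState
from .grid import GridSpec, ScalarField3D

__all__ = [
    "save_snapshot",
    "load_snapshot",
    "export_fields",
    "export_mesh",
    "primordia_to_csv",
    "SnapshotError",
]

SNAPSHOT_VERSION = 1

#: column schema of the primordium log CSV
PRIMORDIA_COLUMNS = ["x", "y", "z", "birth_T", "angle", "generation"]


class SnapshotError(RuntimeError):
    """A snapshot file is missing, corrupt, or from an unknown version."""


def save_snapshot(state: SimulationState, path: str | Path) -> None:
    """Persist a full simulation state (lossless round trip)."""
    grid = state.phi.grid
    with h5py.File(path, "w") as f:
        f.attrs["version"] = SNAPSHOT_VERSION
        f.attrs["T"] = state.T
        f.attrs["summit_z"] = state.summit_z
        f.attrs["rng_seed"] = state.rng_seed
        f.attrs["grid"] = [grid.nx, grid.ny, grid.nz]
        f.attrs["dx"] = grid.dx
        f.attrs["dt_chem"] = grid.dt_chem
        f.attrs["dt_mech"] = grid.dt_mech
        f.create_dataset("phi", data=state.phi.values)
        f.create_dataset("u", data=state.u.values)
        f.create_dataset("v", data=state.v.values)
        n = len(state.primordia)
        prim = np.zeros((n, 6))
        for i, r in enumerate(state.primordia):
            prim[i] = [*r.position, r.birth_T, r.angle, r.generation]
        f.create_dataset("primordia", data=prim)


def load_snapshot(path: str | Path) -> SimulationState:
    """Load a snapshot; raises :class:`SnapshotError` on any defect."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("version", -1))
            if version != SNAPSHOT_VERSION:
                raise SnapshotError(
                    f"snapshot version {version} != supported {SNAPSHOT_VERSION}"
                )
            nx, ny, nz = (int(x) for x in f.attrs["grid"])
            grid = GridSpec(
                nx=nx, ny=ny, nz=nz, dx=float(f.attrs["dx"]),
                dt_chem=float(f.attrs["dt_chem"]), dt_mech=float(f.attrs["dt_mech"]),
            )
            state = SimulationState(
                phi=ScalarField3D(f["phi"][...], grid),
                u=ScalarField3D(f["u"][...], grid),
                v=ScalarField3D(f["v"][...], grid),
                T=int(f.attrs["T"]),
                summit_z=float(f.attrs["summit_z"]),
                rng_seed=int(f.attrs["rng_seed"]),
            )
            for row in f["primordia"][...]:
                state.primordia.append(
                    PrimordiumRecord(
                        position=row[:3].copy(), birth_T=int(row[3]),
                        angle=float(row[4]), generation=int(row[5]),
                    )
                )
            return state
    except SnapshotError:
        raise
    except OSError as exc:
        raise SnapshotError(f"cannot read snapshot {path}: {exc}") from exc


def export_fields(state: SimulationState, path: str | Path) -> None:
    """Write phi, u, v as one legacy-ASCII VTK STRUCTURED_POINTS file."""
    grid = state.phi.grid
    lines = [
        "# vtk DataFile Version 3.0",
        "phyllosim fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.nx} {grid.ny} {grid.nz}",
        f"ORIGIN {0.5 * grid.dx} {0.5 * grid.dx} {0.5 * grid.dx}",
        f"SPACING {grid.dx} {grid.dx} {grid.dx}",
        f"POINT_DATA {grid.nx * grid.ny * grid.nz}",
    ]
    for name, fld in (("phi", state.phi), ("u", state.u), ("v", state.v)):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured points iterate x fastest
        flat = fld.values.transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{x:.9g}" for x in flat[i:i + 6])
                     for i in range(0, len(flat), 6))
    Path(path).write_text("\n".join(lines) + "\n")


def export_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a surface mesh; ``.ply`` via trimesh, otherwise VTK polydata
    with per-vertex H and u attached as point data when present."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(path)
        return
    n = mesh.n_vertices
    lines = [
        "# vtk DataFile Version 3.0",
        "phyllosim surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in mesh.vertices)
    m = len(mesh.faces)
    lines.append(f"POLYGONS {m} {4 * m}")
    lines.extend(f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces)
    scalars = [(nm, arr) for nm, arr in (("H", mesh.H), ("u", mesh.u)) if arr is not None]
    if scalars:
        lines.append(f"POINT_DATA {n}")
        for nm, arr in scalars:
            lines.append(f"SCALARS {nm} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.9g}" for x in arr)
    path.write_text("\n".join(lines) + "\n")


def primordia_to_csv(records: list[PrimordiumRecord], path: str | Path) -> None:
    """Primordium log as CSV with columns ``x,y,z,birth_T,angle,generation``."""
    import pandas as pd

    rows = [
        {
            "x": r.position[0], "y": r.position[1], "z": r.position[2],
            "birth_T": r.birth_T, "angle": r.angle, "generation": r.generation,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PRIMORDIA_COLUMNS).to_csv(path, index=False)
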