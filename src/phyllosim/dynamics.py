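"""The coupled growth engine.

One outer cycle = a fast chemical "pulse" (the BVAM system sets a nearly
stationary morphogen pattern) followed by a long burst of slow mechanical
steps in which the phase field grows and deforms:

    dphi/dt = D_phi lap(dF/dphi) + m u^2 + kappa m G[u] + s_phi
    du/dt   = gamma div(sigma grad dF/du) + G[u] + s_u

``m u^2`` adds mass where the morphogen accumulates, ``G`` is the
tip-growth Gaussian anchored a fixed distance below the rising summit, and
``s_phi``/``s_u`` are constant sources switched on inside fixed
primordia.  ``v`` is untouched by the mechanics.  With all sources off
both equations are pure divergences, so the integrals of phi and u are
conserved to roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .analysis import (
    CandidateSite,
    CandidateTracker,
    PrimordiumRecord,
    adaptive_threshold,
    attach_surface_fields,
    detect_primordia,
    extract_isosurface,
)
from .chemistry import FieldDivergenceError, seed_perturbation
from .config import RunConfig
from .energy import MechParams, energy_density_raw
from .fixtures import initialize_domain
from .grid import GridSpec, ScalarField3D
from .stress import stress_tensor_raw

__all__ = [
    "SimulationState",
    "SimulationTrajectory",
    "mass_source",
    "tip_gaussian",
    "apply_primordium_sources",
    "mech_step",
    "run_simulation",
    "initialize_domain",
    "summit_height",
]


@dataclass
class SimulationState:
    """Full simulator state at one outer-cycle boundary."""

    phi: ScalarField3D
    u: ScalarField3D
    v: ScalarField3D
    T: int = 0
    summit_z: float = 0.0
    primordia: list[PrimordiumRecord] = field(default_factory=list)
    rng_seed: int = 0

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.phi.copy(), self.u.copy(), self.v.copy(), self.T,
            self.summit_z, list(self.primordia), self.rng_seed,
        )


@dataclass
class SimulationTrajectory:
    """Output of :func:`run_simulation`."""

    config: RunConfig
    state: SimulationState
    records: list[PrimordiumRecord]
    logs: list[dict]
    snapshots: list[SimulationState]
    final_sites: list[CandidateSite]
    n_generations: int
    diverged_at: int | None = None

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame(self.logs)


def summit_height(phi: ScalarField3D) -> float:
    """Height of the tissue apex: the phi = 0 crossing on the axis column."""
    grid = phi.grid
    col = phi.values[grid.nx // 2, grid.ny // 2, :]
    z = grid.axis_centers(2)
    inside = np.flatnonzero(col >= 0.0)
    if len(inside) == 0:
        return 0.0
    k = inside[-1]
    if k == len(col) - 1:
        return float(z[k])
    # linear interpolation of the zero crossing between k and k+1
    f0, f1 = col[k], col[k + 1]
    return float(z[k] + (z[k + 1] - z[k]) * f0 / (f0 - f1))


def mass_source(u: ScalarField3D, p: MechParams) -> ScalarField3D:
    """alpha[u] = m u^2: local mass addition driven by the morphogen."""
    return ScalarField3D(p.m * u.values**2, u.grid)


def tip_gaussian(state: SimulationState, p: MechParams, grid: GridSpec | None = None) -> ScalarField3D:
    """Isotropic Gaussian auxin source tracking the dome summit.

    Centred on the axis at ``summit_z - R`` so its distance to the apex
    stays constant while the dome grows; its amplitude rises linearly with
    the summit displacement, ``tip_gain * (summit_z - summit_z(0) + 1)``.
    """
    if grid is None:
        grid = state.phi.grid
    cx, cy = grid.axis_xy
    cz = state.summit_z - p.R
    amplitude = p.tip_gain * (state.summit_z - (p.Hz + p.R) + 1.0)
    amplitude = max(amplitude, 0.0)
    x, y, z = grid.meshgrid()
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    return ScalarField3D(amplitude * np.exp(-d2 / (2.0 * p.g_width**2)), grid)


def apply_primordium_sources(
    state: SimulationState, p: MechParams, grid: GridSpec | None = None
) -> tuple[ScalarField3D, ScalarField3D]:
    """Constant source fields inside balls of radius r_p around each primordium.

    Overlapping balls take the pointwise max (sources do not double-add).
    """
    if grid is None:
        grid = state.phi.grid
    s_phi = np.zeros(grid.shape)
    s_u = np.zeros(grid.shape)
    if state.primordia:
        x, y, z = grid.meshgrid()
        for rec in state.primordia:
            px, py, pz = rec.position
            ball = (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2 <= p.r_p**2
            s_phi[ball] = np.maximum(s_phi[ball], p.s_phi)
            s_u[ball] = np.maximum(s_u[ball], p.s_u)
    return ScalarField3D(s_phi, grid), ScalarField3D(s_u, grid)


class _MechWorkspace:
    """Scratch arrays for the fused mechanical kernel."""

    def __init__(self, shape: tuple[int, int, int]):
        self.arrays = [np.empty(shape) for _ in range(10)]


def _mech_burst(phi, u, sigma, G, s_phi, s_u, ws, n, grid: GridSpec, p: MechParams):
    _kernels.mech_substeps(
        phi, u,
        np.ascontiguousarray(sigma[..., 0, 0]), np.ascontiguousarray(sigma[..., 1, 1]),
        np.ascontiguousarray(sigma[..., 2, 2]), np.ascontiguousarray(sigma[..., 0, 1]),
        np.ascontiguousarray(sigma[..., 0, 2]), np.ascontiguousarray(sigma[..., 1, 2]),
        G, s_phi, s_u, *ws.arrays,
        n, grid.dt_mech, grid.dx, p.eps, p.beta, p.gamma, p.m, p.kappa,
        p.D_phi, p.rho_phi, p.rho_u,
    )


def _symmetrized_stress(phi: np.ndarray, u: np.ndarray, p: MechParams, dx: float) -> np.ndarray:
    sigma = stress_tensor_raw(phi, u, p, dx)
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def mech_step(
    state: SimulationState,
    p: MechParams,
    grid: GridSpec | None = None,
    sigma: np.ndarray | None = None,
    n_steps: int = 1,
) -> SimulationState:
    """Advance ``n_steps`` mechanical Euler steps (sigma fixed throughout).

    Returns a new state; raises :class:`FieldDivergenceError` naming the
    field and cycle if the step produced non-finite values.
    """
    if grid is None:
        grid = state.phi.grid
    new = state.copy()
    if sigma is None:
        sigma = _symmetrized_stress(new.phi.values, new.u.values, p, grid.dx)
    G = tip_gaussian(new, p, grid)
    s_phi, s_u = apply_primordium_sources(new, p, grid)
    ws = _MechWorkspace(grid.shape)
    phi_arr = new.phi.values
    u_arr = new.u.values
    _mech_burst(phi_arr, u_arr, sigma, G.values, s_phi.values, s_u.values,
                ws, n_steps, grid, p)
    for name, arr in (("phi", phi_arr), ("u", u_arr)):
        if not np.all(np.isfinite(arr)):
            raise FieldDivergenceError(
                f"field '{name}' diverged during mechanical stepping at T={state.T}"
            )
    new.summit_z = summit_height(new.phi)
    return new


def run_simulation(
    config: RunConfig,
    progress: bool = False,
    resume_from: SimulationState | None = None,
) -> SimulationTrajectory:
    """Run the full coupled two-time-scale simulation.

    Initialises phi as the tanh dome and (u, v) as seeded noise about
    (0, 0); alternates chemical pulses and mechanical bursts; after every
    cycle extracts the surface, detects candidate accumulation sites and
    fixes those that persist.  Deterministic given (config, seed).

    ``resume_from`` continues a saved state at its stored cycle counter
    (already-fixed primordia are kept; in-flight candidate tracks are not
    part of a snapshot, so resuming is exact when the snapshot predates the
    first candidates).
    """
    grid = config.grid
    chem = config.chem
    mech = config.mech
    sched = config.schedule
    det = config.detection

    if resume_from is None:
        phi = initialize_domain(grid, mech)
        u, v = seed_perturbation(grid, config.seed, sched.noise_amplitude)
        # the morphogens live inside the tissue: mask the seed to phi > 0
        inside0 = phi.values > 0.0
        u.values *= inside0
        v.values *= inside0
        state = SimulationState(phi, u, v, T=0, rng_seed=config.seed)
        state.summit_z = summit_height(phi)
        T_start = 1
    else:
        state = resume_from.copy()
        T_start = state.T + 1

    tracker = CandidateTracker(
        tau=det.tau, track_radius=det.track_radius,
        generation_window=det.generation_window,
    )
    if state.primordia:
        tracker.records = list(state.primordia)
        tracker._gen_first_birth = sorted(
            {min(r.birth_T for r in state.primordia if r.generation == g)
             for g in {r.generation for r in state.primordia}}
        )
    ws = _MechWorkspace(grid.shape)
    du = np.empty(grid.shape)
    dv = np.empty(grid.shape)
    logs: list[dict] = []
    snapshots: list[SimulationState] = []
    final_sites: list[CandidateSite] = []
    cx, cy = grid.axis_xy
    stop_at_T: int | None = None  # settle window once the target generation fixes
    prev_std: float | None = None

    phi_arr = state.phi.values
    u_arr = state.u.values
    v_arr = state.v.values

    diverged_at: int | None = None
    for T in range(T_start, sched.n_cycles + 1):
        state.T = T
        checkpoint = (phi_arr.copy(), u_arr.copy(), v_arr.copy())
        try:
            # --- chemical pulse, confined to the tissue interior ----------
            mask = (phi_arr > 0.0).astype(float)
            with np.errstate(over="ignore", invalid="ignore"):
                _kernels.chem_substeps_masked(u_arr, v_arr, du, dv, mask,
                                              sched.n_chem, grid.dt_chem,
                                              chem.D, chem.a, chem.b,
                                              chem.c, chem.h, chem.eta, grid.dx)
            for name, arr in (("u", u_arr), ("v", v_arr)):
                if not np.all(np.isfinite(arr)):
                    raise FieldDivergenceError(
                        f"field '{name}' diverged during the chemical pulse at T={T}"
                    )
            # --- mechanical burst ----------------------------------------
            state.summit_z = summit_height(state.phi)
            G = tip_gaussian(state, mech, grid).values
            s_phi, s_u = apply_primordium_sources(state, mech, grid)
            remaining = sched.n_mech
            with np.errstate(over="ignore", invalid="ignore"):
                while remaining > 0:
                    n = min(sched.stress_every, remaining)
                    sigma = _symmetrized_stress(phi_arr, u_arr, mech, grid.dx)
                    if not np.all(np.isfinite(sigma)):
                        raise FieldDivergenceError(
                            f"stress tensor diverged at T={T}"
                        )
                    _mech_burst(phi_arr, u_arr, sigma, G, s_phi.values,
                                s_u.values, ws, n, grid, mech)
                    remaining -= n
            for name, arr in (("phi", phi_arr), ("u", u_arr)):
                if not np.all(np.isfinite(arr)):
                    raise FieldDivergenceError(
                        f"field '{name}' diverged during mechanical stepping at T={T}"
                    )
        except FieldDivergenceError:
            if sched.on_divergence == "raise":
                raise
            # truncate: restore the last good cycle and stop
            phi_arr[:], u_arr[:], v_arr[:] = checkpoint
            state.T = T - 1
            diverged_at = T
            break
        state.summit_z = summit_height(state.phi)

        # --- detection and fixation --------------------------------------
        # detection waits for the chemical pattern to settle: candidates on
        # a still-growing pulse drift and would fix at transient positions
        inside = mask > 0.0
        std = float(u_arr[inside].std()) if inside.any() else 0.0
        settled = (
            std > det.min_std
            and prev_std is not None
            and abs(std - prev_std) <= det.stationarity_tol * max(std, 1e-12)
        )
        prev_std = std
        mesh = extract_isosurface(state.phi)
        sites: list[CandidateSite] = []
        if mesh.n_vertices and settled:
            attach_surface_fields(mesh, grid, u=u_arr)
            apex = np.array([cx, cy, state.summit_z])
            # threshold statistics exclude the apex cap: the tip auxin
            # source would otherwise inflate the mean and mask the organs
            away = np.linalg.norm(mesh.vertices - apex, axis=1) >= mech.g_width
            thr = adaptive_threshold(mesh.u[away], det.n_sigma, det.u_floor)
            sites = detect_primordia(
                mesh, thr, apex=apex, exclusion_radius=mech.g_width,
                axis_xy=(cx, cy), merge_radius=det.merge_radius,
            )
        tracker.update(sites, T)
        state.primordia = tracker.records
        final_sites = sites

        logs.append(
            {
                "T": T,
                "F": float(energy_density_raw(phi_arr, u_arr, mech, grid.dx).sum()
                           * grid.voxel_volume),
                "sum_phi": float(phi_arr.sum() * grid.voxel_volume),
                "sum_u": float(u_arr.sum() * grid.voxel_volume),
                "summit_z": state.summit_z,
                "n_candidates": len(sites),
                "n_primordia": len(tracker.records),
                "n_generations": tracker.n_generations,
            }
        )
        if progress:
            print(
                f"T={T:4d} F={logs[-1]['F']:.4g} summit={state.summit_z:.2f} "
                f"sites={len(sites)} fixed={len(tracker.records)}"
            )
        if sched.snapshot_every and T % sched.snapshot_every == 0:
            snapshots.append(state.copy())
        if (sched.stop_after_generations
                and stop_at_T is None
                and tracker.n_generations >= sched.stop_after_generations
                and len(tracker.records) >= 1):
            # let the rest of the ring cross the persistence threshold
            stop_at_T = T + det.tau + 5
        if stop_at_T is not None and T >= stop_at_T:
            break

    if not tracker.records and not final_sites:
        # nothing ever settled enough to fix: report the surface sites of
        # the final state so callers can still read off the pattern
        mesh = extract_isosurface(state.phi)
        if mesh.n_vertices:
            attach_surface_fields(mesh, grid, u=u_arr)
            apex = np.array([cx, cy, state.summit_z])
            away = np.linalg.norm(mesh.vertices - apex, axis=1) >= mech.g_width
            thr = adaptive_threshold(mesh.u[away], det.n_sigma, det.u_floor)
            final_sites = detect_primordia(
                mesh, thr, apex=apex, exclusion_radius=mech.g_width,
                axis_xy=(cx, cy), merge_radius=det.merge_radius,
            )

    return SimulationTrajectory(
        config=config,
        state=state,
        records=tracker.records,
        logs=logs,
        snapshots=snapshots,
        final_sites=final_sites,
        n_generations=tracker.n_generations,
        diverged_at=diverged_at,
    )
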