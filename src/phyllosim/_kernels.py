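"""Fused numba kernels for the two inner time-stepping loops.

These duplicate, loop-fused, the reference numpy operations in
:mod:`phyllosim.calculus` / :mod:`phyllosim.energy`: the chemical Euler
step and the mechanical Euler step (phase-field + stress-directed
transport).  ``fastmath`` is off so results stay reproducible; the test
suite pins the kernels against the numpy path.

Index convention: mirror (even) ghosts for scalars -- implemented by
clamping neighbour indices -- and zero flux through boundary faces in the
finite-volume transport term, matching the reference operators exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def chem_substeps(u, v, du, dv, n, dt, D, a, b, c, h, eta, dx):
    """n explicit Euler steps of the BVAM reaction-diffusion system."""
    inv2 = 1.0 / (dx * dx)
    NX, NY, NZ = u.shape
    for _ in range(n):
        for i in range(NX):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < NX - 1 else NX - 1
            for j in range(NY):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < NY - 1 else NY - 1
                for k in range(NZ):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < NZ - 1 else NZ - 1
                    uc = u[i, j, k]
                    vc = v[i, j, k]
                    lu = (u[ip, j, k] + u[im, j, k] + u[i, jp, k] + u[i, jm, k]
                          + u[i, j, kp] + u[i, j, km] - 6.0 * uc) * inv2
                    lv = (v[ip, j, k] + v[im, j, k] + v[i, jp, k] + v[i, jm, k]
                          + v[i, j, kp] + v[i, j, km] - 6.0 * vc) * inv2
                    uv = uc * vc
                    uvv = uv * vc
                    du[i, j, k] = D * lu + eta * (uc + a * vc - c * uv - uvv)
                    dv[i, j, k] = lv + eta * (b * vc + h * uc + c * uv + uvv)
        for i in range(NX):
            for j in range(NY):
                for k in range(NZ):
                    u[i, j, k] += dt * du[i, j, k]
                    v[i, j, k] += dt * dv[i, j, k]


@njit(cache=True)
def chem_substeps_masked(u, v, du, dv, mask, n, dt, D, a, b, c, h, eta, dx):
    """n BVAM Euler steps confined to the tissue interior.

    ``mask`` is 1.0 inside (phi > 0), 0.0 outside.  Diffusion is in
    finite-volume form with faces closed wherever either side is outside,
    which is the discrete zero-flux condition on the phi = 0 surface;
    kinetics act only inside, and outside voxels are left untouched.
    """
    inv2 = 1.0 / (dx * dx)
    NX, NY, NZ = u.shape
    for _ in range(n):
        for i in range(NX):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < NX - 1 else NX - 1
            for j in range(NY):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < NY - 1 else NY - 1
                for k in range(NZ):
                    if mask[i, j, k] == 0.0:
                        du[i, j, k] = 0.0
                        dv[i, j, k] = 0.0
                        continue
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < NZ - 1 else NZ - 1
                    uc = u[i, j, k]
                    vc = v[i, j, k]
                    lu = (mask[ip, j, k] * (u[ip, j, k] - uc)
                          + mask[im, j, k] * (u[im, j, k] - uc)
                          + mask[i, jp, k] * (u[i, jp, k] - uc)
                          + mask[i, jm, k] * (u[i, jm, k] - uc)
                          + mask[i, j, kp] * (u[i, j, kp] - uc)
                          + mask[i, j, km] * (u[i, j, km] - uc)) * inv2
                    lv = (mask[ip, j, k] * (v[ip, j, k] - vc)
                          + mask[im, j, k] * (v[im, j, k] - vc)
                          + mask[i, jp, k] * (v[i, jp, k] - vc)
                          + mask[i, jm, k] * (v[i, jm, k] - vc)
                          + mask[i, j, kp] * (v[i, j, kp] - vc)
                          + mask[i, j, km] * (v[i, j, km] - vc)) * inv2
                    uv = uc * vc
                    uvv = uv * vc
                    du[i, j, k] = D * lu + eta * (uc + a * vc - c * uv - uvv)
                    dv[i, j, k] = lv + eta * (b * vc + h * uc + c * uv + uvv)
        for i in range(NX):
            for j in range(NY):
                for k in range(NZ):
                    u[i, j, k] += dt * du[i, j, k]
                    v[i, j, k] += dt * dv[i, j, k]


@njit(cache=True)
def _lap_into(f, out, inv2):
    NX, NY, NZ = f.shape
    for i in range(NX):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < NX - 1 else NX - 1
        for j in range(NY):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < NY - 1 else NY - 1
            for k in range(NZ):
                km = k - 1 if k > 0 else 0
                kp = k + 1 if k < NZ - 1 else NZ - 1
                out[i, j, k] = (f[ip, j, k] + f[im, j, k] + f[i, jp, k] + f[i, jm, k]
                                + f[i, j, kp] + f[i, j, km] - 6.0 * f[i, j, k]) * inv2


@njit(cache=True)
def _grad_into(f, gx, gy, gz, invd):
    NX, NY, NZ = f.shape
    for i in range(NX):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < NX - 1 else NX - 1
        for j in range(NY):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < NY - 1 else NY - 1
            for k in range(NZ):
                km = k - 1 if k > 0 else 0
                kp = k + 1 if k < NZ - 1 else NZ - 1
                gx[i, j, k] = (f[ip, j, k] - f[im, j, k]) * invd
                gy[i, j, k] = (f[i, jp, k] - f[i, jm, k]) * invd
                gz[i, j, k] = (f[i, j, kp] - f[i, j, km]) * invd


@njit(cache=True)
def mech_substeps(phi, u, sxx, syy, szz, sxy, sxz, syz, G, sphi, su,
                  psc, lap_phi, mu_phi, lap_mu, mu_u, gx, gy, gz, dphi, dut,
                  n, dt, dx, eps, beta, gamma, m, kappa, D_phi, rho_phi, rho_u):
    """n explicit Euler steps of the coupled mechanical equations.

    phi += dt [ D_phi lap(dF/dphi) + m u^2 + kappa m G + sphi ]
    u   += dt [ gamma div(sigma grad dF/du) + G + su ]

    sigma (six symmetric components) is held fixed for the burst; the
    caller recomputes it at its chosen cadence.
    """
    inv2 = 1.0 / (dx * dx)
    invd = 0.5 / dx
    e2 = eps * eps
    NX, NY, NZ = phi.shape
    for _ in range(n):
        _lap_into(phi, lap_phi, inv2)
        for i in range(NX):
            for j in range(NY):
                for k in range(NZ):
                    ph = phi[i, j, k]
                    uu = u[i, j, k]
                    psc[i, j, k] = (-ph + ph * ph * ph - e2 * lap_phi[i, j, k]
                                    - eps * beta * uu * uu * (ph * ph - 1.0))
        _lap_into(psc, mu_phi, inv2)  # mu_phi temporarily holds lap(psc)
        for i in range(NX):
            for j in range(NY):
                for k in range(NZ):
                    ph = phi[i, j, k]
                    uu = u[i, j, k]
                    bulk = 3.0 * ph * ph - 1.0 - 2.0 * ph * eps * beta * uu * uu
                    mu_phi[i, j, k] = (2.0 * (bulk * psc[i, j, k] - e2 * mu_phi[i, j, k])
                                       + rho_phi * lap_phi[i, j, k])
        _lap_into(mu_phi, lap_mu, inv2)
        _lap_into(u, mu_u, inv2)  # mu_u temporarily holds lap(u)
        for i in range(NX):
            for j in range(NY):
                for k in range(NZ):
                    ph = phi[i, j, k]
                    uu = u[i, j, k]
                    mu_u[i, j, k] = (-4.0 * eps * (ph * ph - 1.0) * beta * uu * psc[i, j, k]
                                     + rho_u * mu_u[i, j, k])
        _grad_into(mu_u, gx, gy, gz, invd)
        # finite-volume divergence of sigma grad(mu_u); zero boundary faces
        for i in range(NX):
            for j in range(NY):
                for k in range(NZ):
                    acc = 0.0
                    # x faces
                    if i < NX - 1:
                        acc += (0.5 * (sxx[i, j, k] + sxx[i + 1, j, k])
                                * (mu_u[i + 1, j, k] - mu_u[i, j, k]) / dx
                                + 0.5 * (sxy[i, j, k] * gy[i, j, k]
                                         + sxy[i + 1, j, k] * gy[i + 1, j, k])
                                + 0.5 * (sxz[i, j, k] * gz[i, j, k]
                                         + sxz[i + 1, j, k] * gz[i + 1, j, k]))
                    if i > 0:
                        acc -= (0.5 * (sxx[i - 1, j, k] + sxx[i, j, k])
                                * (mu_u[i, j, k] - mu_u[i - 1, j, k]) / dx
                                + 0.5 * (sxy[i - 1, j, k] * gy[i - 1, j, k]
                                         + sxy[i, j, k] * gy[i, j, k])
                                + 0.5 * (sxz[i - 1, j, k] * gz[i - 1, j, k]
                                         + sxz[i, j, k] * gz[i, j, k]))
                    # y faces
                    if j < NY - 1:
                        acc += (0.5 * (syy[i, j, k] + syy[i, j + 1, k])
                                * (mu_u[i, j + 1, k] - mu_u[i, j, k]) / dx
                                + 0.5 * (sxy[i, j, k] * gx[i, j, k]
                                         + sxy[i, j + 1, k] * gx[i, j + 1, k])
                                + 0.5 * (syz[i, j, k] * gz[i, j, k]
                                         + syz[i, j + 1, k] * gz[i, j + 1, k]))
                    if j > 0:
                        acc -= (0.5 * (syy[i, j - 1, k] + syy[i, j, k])
                                * (mu_u[i, j, k] - mu_u[i, j - 1, k]) / dx
                                + 0.5 * (sxy[i, j - 1, k] * gx[i, j - 1, k]
                                         + sxy[i, j, k] * gx[i, j, k])
                                + 0.5 * (syz[i, j - 1, k] * gz[i, j - 1, k]
                                         + syz[i, j, k] * gz[i, j, k]))
                    # z faces
                    if k < NZ - 1:
                        acc += (0.5 * (szz[i, j, k] + szz[i, j, k + 1])
                                * (mu_u[i, j, k + 1] - mu_u[i, j, k]) / dx
                                + 0.5 * (sxz[i, j, k] * gx[i, j, k]
                                         + sxz[i, j, k + 1] * gx[i, j, k + 1])
                                + 0.5 * (syz[i, j, k] * gy[i, j, k]
                                         + syz[i, j, k + 1] * gy[i, j, k + 1]))
                    if k > 0:
                        acc -= (0.5 * (szz[i, j, k - 1] + szz[i, j, k])
                                * (mu_u[i, j, k] - mu_u[i, j, k - 1]) / dx
                                + 0.5 * (sxz[i, j, k - 1] * gx[i, j, k - 1]
                                         + sxz[i, j, k] * gx[i, j, k])
                                + 0.5 * (syz[i, j, k - 1] * gy[i, j, k - 1]
                                         + syz[i, j, k] * gy[i, j, k]))
                    uu = u[i, j, k]
                    ph = phi[i, j, k]
                    # mass addition is interface-localized: (1 - phi^2)
                    # vanishes in both bulk phases and pulls back phi > 1,
                    # so growth advances the surface instead of piling
                    # density into the interior
                    loc = 1.0 - ph * ph
                    dphi[i, j, k] = (D_phi * lap_mu[i, j, k]
                                     + (m * uu * uu + kappa * m * G[i, j, k]) * loc
                                     + sphi[i, j, k])
                    dut[i, j, k] = gamma * acc / dx + G[i, j, k] + su[i, j, k]
        for i in range(NX):
            for j in range(NY):
                for k in range(NZ):
                    phi[i, j, k] += dt * dphi[i, j, k]
                    u[i, j, k] += dt * dut[i, j, k]
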