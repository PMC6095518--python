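"""Free energy, spontaneous curvature, and variational derivatives."""

import numpy as np
import pytest

import phyllosim as ps
from phyllosim.energy import dF_dphi_raw, dF_du_raw, energy_density_raw


def mech(**kw):
    return ps.MechParams(**kw)


def tanh_1d_grid(n=64, L=32.0):
    grid = ps.GridSpec(nx=n, ny=8, nz=8, dx=L / n)
    phi = ps.ScalarField3D.from_function(
        grid, lambda x, y, z: np.tanh((x - L / 2) / np.sqrt(2.0))
    )
    return grid, phi


class TestPhiFunctional:
    @pytest.mark.parametrize("bulk", [1.0, -1.0])
    def test_bulk_phases_are_roots(self, small_grid, bulk):
        phi = ps.ScalarField3D.full(small_grid, bulk)
        assert np.allclose(ps.phi_functional(phi, mech()).values, 0.0, atol=1e-12)

    def test_midpoint_value(self, small_grid):
        phi = ps.ScalarField3D.full(small_grid, 0.5)
        out = ps.phi_functional(phi, mech()).values
        assert np.allclose(out, -0.375, atol=1e-12)


class TestSpontaneousCurvature:
    def test_zero_morphogen_and_zero_coupling(self, small_grid, rng):
        u0 = ps.ScalarField3D.full(small_grid)
        assert np.allclose(ps.spontaneous_curvature(u0, mech()).values, 0.0)
        u = ps.ScalarField3D(rng.normal(size=small_grid.shape), small_grid)
        assert np.allclose(ps.spontaneous_curvature(u, mech(beta=0.0)).values, 0.0)

    def test_unit_morphogen(self, small_grid):
        u = ps.ScalarField3D.full(small_grid, 1.0)
        out = ps.spontaneous_curvature(u, mech(beta=0.5)).values
        assert np.allclose(out, 0.5)


class TestPhiSC:
    def test_reduces_to_phi_functional_without_morphogen(self, small_grid, rng):
        phi = ps.ScalarField3D(np.tanh(rng.normal(size=small_grid.shape)), small_grid)
        u0 = ps.ScalarField3D.full(small_grid)
        p = mech()
        assert np.allclose(
            ps.phi_sc(phi, u0, p).values, ps.phi_functional(phi, p).values
        )

    def test_bulk_insulation(self, small_grid, rng):
        # (phi^2 - 1) kills the coupling in either bulk phase for any u
        u = ps.ScalarField3D(rng.normal(size=small_grid.shape), small_grid)
        p = mech(beta=0.7)
        for bulk in (1.0, -1.0):
            phi = ps.ScalarField3D.full(small_grid, bulk)
            assert np.allclose(
                ps.phi_sc(phi, u, p).values, ps.phi_functional(phi, p).values,
                atol=1e-12,
            )

    def test_hand_value_at_interface_midplane(self, small_grid):
        phi = ps.ScalarField3D.full(small_grid, 0.0)
        u = ps.ScalarField3D.full(small_grid, 1.0)
        out = ps.phi_sc(phi, u, mech(beta=0.5, eps=1.0)).values
        # Phi = 0, then - eps * beta * (0 - 1) = +0.5
        assert np.allclose(out, 0.5, atol=1e-12)


class TestFreeEnergy:
    def test_bulk_states_have_zero_energy(self, small_grid):
        p = mech()
        phi = ps.ScalarField3D.full(small_grid, 1.0)
        for uval in (0.0, 0.8):
            u = ps.ScalarField3D.full(small_grid, uval)
            ef = ps.free_energy(phi, u, p)
            assert ef.F == pytest.approx(0.0, abs=1e-12)

    def test_equilibrium_tanh_profile_has_small_residual(self):
        # Phi[phi] = 0 along tanh(x / sqrt(2) eps); the discrete residual is
        # truncation error and shrinks under refinement
        p = mech(rho_phi=0.0, rho_u=0.0, beta=0.0)
        residuals = []
        for n in (32, 64):
            grid, phi = tanh_1d_grid(n=n)
            u = ps.ScalarField3D.full(grid)
            ef = ps.free_energy(phi, u, p)
            residuals.append(abs(ef.F))
        assert residuals[1] < residuals[0] / 4
        assert residuals[1] < 1e-3 * 8 * 8 * 32


class TestVariationalDerivatives:
    def test_bulk_equilibrium_gradients_vanish(self, small_grid):
        p = mech()
        phi = ps.ScalarField3D.full(small_grid, 1.0)
        u = ps.ScalarField3D.full(small_grid)
        assert np.allclose(ps.dF_dphi(phi, u, p).values, 0.0, atol=1e-12)
        assert np.allclose(ps.dF_du(phi, u, p).values, 0.0, atol=1e-12)

    def test_dF_du_zero_morphogen(self, small_grid, rng):
        p = mech()
        phi = ps.ScalarField3D(np.tanh(rng.normal(size=small_grid.shape)), small_grid)
        u0 = ps.ScalarField3D.full(small_grid)
        assert np.allclose(ps.dF_du(phi, u0, p).values, 0.0, atol=1e-12)

    def test_dF_du_bulk_reduces_to_diffusion_term(self, small_grid, rng):
        p = mech()
        u = ps.ScalarField3D(rng.normal(size=small_grid.shape), small_grid)
        phi = ps.ScalarField3D.full(small_grid, -1.0)
        expected = p.rho_u * ps.laplacian(u).values
        assert np.allclose(ps.dF_du(phi, u, p).values, expected, atol=1e-12)

    def test_tanh_profile_residual_vanishes_under_refinement(self):
        # mu = 0 along the continuum equilibrium profile; the discrete
        # residual is truncation error and falls roughly 4x per dx halving
        p = mech(rho_phi=0.0, rho_u=0.0, beta=0.0)
        res = []
        for n in (64, 256):
            grid, phi = tanh_1d_grid(n=n)
            u = ps.ScalarField3D.full(grid)
            mu = ps.dF_dphi(phi, u, p).values
            res.append(np.abs(mu[4:-4]).max())
        assert res[0] < 0.2
        assert res[1] < res[0] / 6

    @pytest.mark.parametrize("which", ["phi", "u"])
    def test_matches_numerical_perturbation_of_F(self, small_grid, which):
        # single-voxel central difference of the discrete F is the oracle
        rng = np.random.default_rng(11)
        p = mech(beta=0.5)
        dx3 = small_grid.voxel_volume
        n_checks = 0
        for trial in range(20):
            phi = np.tanh(rng.normal(scale=0.8, size=small_grid.shape))
            u = 0.5 * rng.normal(size=small_grid.shape)
            mu = (dF_dphi_raw if which == "phi" else dF_du_raw)(
                phi, u, p, small_grid.dx
            )
            i, j, k = rng.integers(2, 14, size=3)
            delta = 1e-6
            tgt = phi if which == "phi" else u

            def total(arr):
                return energy_density_raw(phi, u, p, small_grid.dx).sum() * dx3

            tgt[i, j, k] += delta
            fp = total(None)
            tgt[i, j, k] -= 2 * delta
            fm = total(None)
            tgt[i, j, k] += delta
            numeric = (fp - fm) / (2 * delta * dx3)
            scale = max(np.abs(mu).max(), 1e-6)
            assert abs(mu[i, j, k] - numeric) <= 1e-4 * scale
            n_checks += 1
        assert n_checks == 20

    def test_beta_zero_reduces_to_ginzburg_landau(self, small_grid, rng):
        # with beta = 0 the whole energy is the pure Phi^2 theory: u only
        # enters through its own tension term
        p0 = mech(beta=0.0)
        phi = ps.ScalarField3D(np.tanh(rng.normal(size=small_grid.shape)), small_grid)
        u = ps.ScalarField3D(rng.normal(size=small_grid.shape), small_grid)
        u0 = ps.ScalarField3D.full(small_grid)
        mu_with = ps.dF_dphi(phi, u, p0).values
        mu_without = ps.dF_dphi(phi, u0, p0).values
        assert np.allclose(mu_with, mu_without, atol=1e-12)
        assert np.allclose(
            ps.dF_du(phi, u, p0).values, p0.rho_u * ps.laplacian(u).values,
            atol=1e-12,
        )
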