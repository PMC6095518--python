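"""Growth engine: sources, tip growth, conservation, determinism."""

import numpy as np
import pytest

import phyllosim as ps
from phyllosim.chemistry import FieldDivergenceError
from phyllosim.dynamics import SimulationState, summit_height


def mech(**kw):
    return ps.MechParams(**kw)


def dome_state(grid, p=None, u_val=0.0):
    p = p or mech()
    phi = ps.initialize_domain(grid, p)
    state = SimulationState(
        phi=phi,
        u=ps.ScalarField3D.full(grid, u_val),
        v=ps.ScalarField3D.full(grid),
    )
    state.summit_z = summit_height(phi)
    return state


class TestMassSource:
    def test_zero_morphogen_and_zero_rate(self, small_grid, rng):
        p = mech()
        u0 = ps.ScalarField3D.full(small_grid)
        assert np.allclose(ps.mass_source(u0, p).values, 0.0)
        u = ps.ScalarField3D(rng.normal(size=small_grid.shape), small_grid)
        assert np.allclose(ps.mass_source(u, mech(m=0.0)).values, 0.0)

    def test_published_rate(self, small_grid):
        u = ps.ScalarField3D.full(small_grid, 1.0)
        assert np.allclose(ps.mass_source(u, mech()).values, 15.0)


class TestTipGaussian:
    def test_gaussian_profile_against_analytic_form(self, default_grid):
        p = mech()
        state = dome_state(default_grid, p)
        G = ps.tip_gaussian(state, p).values
        cx, cy = default_grid.axis_xy
        x, y, z = default_grid.meshgrid()
        cz = state.summit_z - p.R
        amplitude = p.tip_gain * (state.summit_z - (p.Hz + p.R) + 1.0)
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        expected = amplitude * np.exp(-d2 / (2 * p.g_width**2))
        assert np.allclose(G, expected, atol=1e-12)
        # one standard deviation from the centre the value is A e^{-1/2}
        assert expected.max() == pytest.approx(amplitude, rel=0.05)

    def test_monotone_decay_with_distance(self, default_grid):
        p = mech()
        state = dome_state(default_grid, p)
        G = ps.tip_gaussian(state, p).values
        i, j = default_grid.nx // 2, default_grid.ny // 2
        cz_k = int(state.summit_z - p.R)
        profile = G[i:, j, cz_k]
        assert np.all(np.diff(profile) <= 1e-15)

    def test_center_tracks_rising_summit(self, default_grid):
        p = mech()
        state = dome_state(default_grid, p)
        G1 = ps.tip_gaussian(state, p).values
        state.summit_z += 2.0
        G2 = ps.tip_gaussian(state, p).values
        k1 = np.argmax(G1[default_grid.nx // 2, default_grid.ny // 2])
        k2 = np.argmax(G2[default_grid.nx // 2, default_grid.ny // 2])
        assert k2 > k1


class TestPrimordiumSources:
    def test_no_primordia_gives_zero_fields(self, default_grid):
        p = mech()
        state = dome_state(default_grid, p)
        s_phi, s_u = ps.apply_primordium_sources(state, p)
        assert np.allclose(s_phi.values, 0.0) and np.allclose(s_u.values, 0.0)

    def test_single_source_ball_support(self, default_grid):
        p = mech()
        state = dome_state(default_grid, p)
        state.primordia.append(
            ps.PrimordiumRecord(np.array([20.0, 10.0, 6.0]), 1, 0.0, 0)
        )
        s_phi, _ = ps.apply_primordium_sources(state, p)
        support = np.count_nonzero(s_phi.values)
        x, y, z = default_grid.meshgrid()
        ball = ((x - 20) ** 2 + (y - 10) ** 2 + (z - 6) ** 2) <= p.r_p**2
        assert support == ball.sum()
        assert np.all(s_phi.values[ball] == p.s_phi)

    def test_overlapping_sources_do_not_double_add(self, default_grid):
        p = mech()
        state = dome_state(default_grid, p)
        for pos in ([20.0, 10.0, 6.0], [21.0, 10.0, 6.0]):
            state.primordia.append(
                ps.PrimordiumRecord(np.array(pos), 1, 0.0, 0)
            )
        _, s_u = ps.apply_primordium_sources(state, p)
        assert s_u.values.max() == pytest.approx(p.s_u)


class TestMechStep:
    def test_equilibrium_state_is_stationary(self, small_grid):
        p = mech(beta=0.0, m=0.0, kappa=0.0, tip_gain=0.0, s_phi=0.0, s_u=0.0)
        for bulk in (1.0, -1.0):
            state = SimulationState(
                phi=ps.ScalarField3D.full(small_grid, bulk),
                u=ps.ScalarField3D.full(small_grid),
                v=ps.ScalarField3D.full(small_grid),
            )
            new = ps.mech_step(state, p, small_grid)
            assert np.allclose(new.phi.values, state.phi.values, atol=1e-14)
            assert np.allclose(new.u.values, state.u.values, atol=1e-14)

    def test_conservation_with_sources_off(self, default_grid):
        # pure divergences: both integrals conserved over 1000 steps
        p = mech(m=0.0, kappa=0.0, tip_gain=0.0, s_phi=0.0, s_u=0.0)
        state = dome_state(default_grid, p)
        rng = np.random.default_rng(0)
        inside = state.phi.values > 0
        state.u.values[:] = 0.3 * rng.normal(size=default_grid.shape) * inside
        phi0 = state.phi.integral()
        u0 = state.u.integral()
        new = ps.mech_step(state, p, default_grid, n_steps=1000)
        assert new.phi.integral() == pytest.approx(phi0, rel=1e-8)
        assert new.u.integral() == pytest.approx(u0, abs=1e-8 * abs(phi0))

    def test_divergence_error_names_field(self, small_grid):
        p = mech()
        state = SimulationState(
            phi=ps.ScalarField3D.full(small_grid, 1.0),
            u=ps.ScalarField3D.full(small_grid),
            v=ps.ScalarField3D.full(small_grid),
        )
        state.phi.values[5, 5, 5] = 1e120  # guaranteed overflow
        with pytest.raises(FieldDivergenceError, match="phi|u"):
            with np.errstate(all="ignore"):
                ps.mech_step(state, p, small_grid, n_steps=3)


class TestInitializeDomain:
    def test_bulk_limits(self, default_grid):
        phi = ps.initialize_domain(default_grid, mech())
        assert phi.values[0, 0, -1] == pytest.approx(-1.0, abs=1e-6)
        assert phi.values[20, 20, 3] == pytest.approx(1.0, abs=1e-3)

    def test_zero_level_set_near_analytic_surface(self, default_grid):
        p = mech()
        phi = ps.initialize_domain(default_grid, p)
        mesh = ps.extract_isosurface(phi)
        cx, cy = default_grid.axis_xy
        v = mesh.vertices
        lateral = v[v[:, 2] < p.Hz - 1.0]
        r = np.hypot(lateral[:, 0] - cx, lateral[:, 1] - cy)
        assert np.abs(r - p.R).max() < 0.5 * default_grid.dx

    def test_summit_is_cylinder_plus_radius(self, default_grid):
        p = mech()
        phi = ps.initialize_domain(default_grid, p)
        assert summit_height(phi) == pytest.approx(p.Hz + p.R, abs=0.5)

    def test_oversized_dome_rejected(self):
        grid = ps.GridSpec(nx=20, ny=20, nz=20)
        with pytest.raises(ValueError):
            ps.initialize_domain(grid, mech(R=10.0, Hz=6.0))


class TestRunDeterminism:
    def test_identical_config_gives_bit_identical_trajectory(self):
        cfg = ps.RunConfig(
            chem=ps.BVAMParams(eta=0.3902, c=0.57),
            schedule=ps.ScheduleParams(n_chem=30, n_mech=20, n_cycles=3,
                                       stress_every=10),
            seed=7,
        )
        t1 = ps.run_simulation(cfg)
        t2 = ps.run_simulation(cfg)
        assert np.array_equal(t1.state.phi.values, t2.state.phi.values)
        assert np.array_equal(t1.state.u.values, t2.state.u.values)
        assert np.array_equal(t1.state.v.values, t2.state.v.values)

    def test_different_seeds_differ(self):
        base = dict(
            chem=ps.BVAMParams(eta=0.3902, c=0.57),
            schedule=ps.ScheduleParams(n_chem=30, n_mech=20, n_cycles=2,
                                       stress_every=10),
        )
        t1 = ps.run_simulation(ps.RunConfig(seed=1, **base))
        t2 = ps.run_simulation(ps.RunConfig(seed=2, **base))
        assert not np.array_equal(t1.state.u.values, t2.state.u.values)
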