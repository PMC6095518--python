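"""Surface extraction, detection, tracking, symmetry counting, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phyllosim as ps
from phyllosim.analysis import (CandidateSite, CandidateTracker,
                                adaptive_threshold, attach_surface_fields,
                                azimuthal_groups, dominant_fourier_mode)


class TestIsosurface:
    def test_sphere_radius_and_topology(self, default_grid):
        phi = ps.make_fixture("sphere", default_grid, radius=8.0)
        mesh = ps.extract_isosurface(phi)
        cx, cy = default_grid.axis_xy
        center = np.array([cx, cy, 0.5 * default_grid.nz * default_grid.dx])
        r = np.linalg.norm(mesh.vertices - center, axis=1)
        assert abs(r.mean() - 8.0) < 0.5 * default_grid.dx
        assert mesh.euler_characteristic() == 2
        assert mesh.n_components() == 1

    def test_no_crossing_gives_empty_mesh(self, small_grid):
        phi = ps.ScalarField3D.full(small_grid, 1.0)
        mesh = ps.extract_isosurface(phi)
        assert mesh.n_vertices == 0

    def test_dome_is_single_component(self, default_grid):
        phi = ps.make_fixture("dome", default_grid)
        assert ps.extract_isosurface(phi).n_components() == 1

    def test_deterministic(self, default_grid):
        phi = ps.make_fixture("dome", default_grid)
        m1 = ps.extract_isosurface(phi)
        m2 = ps.extract_isosurface(phi)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)


class TestSurfaceCurvature:
    def test_sphere(self, default_grid):
        phi = ps.make_fixture("sphere", default_grid, radius=10.0)
        H = ps.surface_mean_curvature(phi)
        valid = np.isfinite(H)
        assert np.nanmedian(H[valid]) == pytest.approx(0.1, rel=0.05)

    def test_plane(self, default_grid):
        phi = ps.make_fixture("plane", default_grid, z0=30.0)
        H = ps.surface_mean_curvature(phi)
        assert np.abs(H[np.isfinite(H)]).max() < 1e-6

    def test_curvature_gradient_peaks_at_dome_junction(self, default_grid):
        # |dH/dz| along the meridian is largest near the cylinder-hemisphere
        # junction where H jumps from 1/(2R) to 1/R
        p = ps.MechParams()
        phi = ps.make_fixture("dome", default_grid, R=p.R, Hz=p.Hz)
        mesh = ps.extract_isosurface(phi)
        H = ps.surface_mean_curvature(phi, mesh)
        z = mesh.vertices[:, 2]
        sel = np.isfinite(H) & (z > 1.0) & (z < p.Hz + p.R - 1.0)
        bins = np.arange(1.0, p.Hz + p.R - 1.0, 1.0)
        idx = np.digitize(z[sel], bins)
        prof = np.array([np.median(H[sel][idx == i])
                         for i in range(1, len(bins))])
        grad = np.abs(np.diff(prof))
        peak_z = bins[1:-1][np.argmax(grad)]
        assert abs(peak_z - p.Hz) <= 3.0


class TestDetection:
    def test_bump_fixture_counts(self, default_grid):
        mesh = ps.make_fixture("bumps", default_grid, k=5, height=8.0)
        thr = adaptive_threshold(mesh.u, floor=0.05)
        cx, cy = default_grid.axis_xy
        sites = ps.detect_primordia(mesh, thr, axis_xy=(cx, cy))
        assert len(sites) == 5

    def test_uniform_subthreshold_field_gives_no_sites(self, default_grid):
        mesh = ps.make_fixture("bumps", default_grid, k=3, amplitude=0.0)
        sites = ps.detect_primordia(mesh, 0.2)
        assert sites == []

    def test_bridged_bumps_merge_into_one_site(self, default_grid):
        # two bumps close enough that their threshold sets connect
        mesh = ps.make_fixture("bumps", default_grid, k=2, height=8.0,
                               bump_width=6.0)
        cx, cy = default_grid.axis_xy
        # k=2 puts bumps at opposite azimuths; widen until they bridge at
        # the threshold: use a low threshold to force connectivity
        sites = ps.detect_primordia(mesh, 0.05 * mesh.u.max(),
                                    axis_xy=(cx, cy), merge_radius=0.0)
        assert len(sites) <= 2
        sites_hi = ps.detect_primordia(mesh, 0.8 * mesh.u.max(),
                                       axis_xy=(cx, cy), merge_radius=0.0)
        assert len(sites_hi) == 2

    def test_apex_exclusion(self, default_grid):
        mesh = ps.make_fixture("bumps", default_grid, k=1, height=15.5,
                               bump_width=1.5)
        cx, cy = default_grid.axis_xy
        apex = np.array([cx, cy, 16.0])
        thr = adaptive_threshold(mesh.u, floor=0.05)
        with_excl = ps.detect_primordia(mesh, thr, apex=apex,
                                        exclusion_radius=8.0, axis_xy=(cx, cy))
        without = ps.detect_primordia(mesh, thr, axis_xy=(cx, cy))
        assert len(without) >= 1
        assert len(with_excl) < len(without)


class TestTracker:
    def site(self, x=20.0, y=10.0, z=6.0):
        angle = float(np.mod(np.arctan2(y - 20.0, x - 20.0), 2 * np.pi))
        return CandidateSite(np.array([x, y, z]), angle, z, 1.0, 5)

    def test_transient_candidate_never_fixes(self):
        tr = CandidateTracker(tau=5)
        assert tr.update([self.site()], 1) == []
        assert tr.update([], 2) == []
        for T in range(3, 10):
            assert tr.update([], T) == []
        assert tr.records == []

    def test_persistent_candidate_fixes_at_tau(self):
        tr = CandidateTracker(tau=5)
        fixed = []
        for T in range(1, 7):
            fixed = tr.update([self.site()], T)
            if fixed:
                break
        assert T == 5 and len(tr.records) == 1

    def test_fixed_record_is_permanent(self):
        tr = CandidateTracker(tau=2)
        tr.update([self.site()], 1)
        tr.update([self.site()], 2)
        assert len(tr.records) == 1
        for T in range(3, 8):
            tr.update([], T)  # candidate gone; record must survive
        assert len(tr.records) == 1

    def test_generation_window_groups_births(self):
        tr = CandidateTracker(tau=1, generation_window=10)
        tr.update([self.site()], 1)
        tr.update([self.site(x=10.0)], 5)  # same generation
        tr.update([self.site(y=30.0)], 40)  # new generation
        gens = [r.generation for r in tr.records]
        assert gens == [0, 0, 1]
        assert tr.n_generations == 2


class TestSymmetry:
    def test_perfect_whorl(self):
        angles = np.deg2rad([0, 90, 180, 270])
        assert ps.count_symmetry(angles) == 4

    def test_jittered_whorl(self, rng):
        base = np.deg2rad([0, 90, 180, 270])
        jitter = np.deg2rad(rng.uniform(-5, 5, 4))
        assert ps.count_symmetry(base + jitter) == 4

    def test_single_site(self):
        assert ps.count_symmetry([0.3]) == 1

    def test_interleaved_rings_fall_back_to_fourier(self):
        # a 3-ring and a 25-degree-offset copy: six sites that are not a
        # coherent 6-fold whorl; the dominant mode is 3
        angles = np.deg2rad([0, 25, 120, 145, 240, 265])
        assert ps.count_symmetry(angles) == 3

    @given(shift=st.floats(0, 2 * np.pi))
    @settings(max_examples=30, deadline=None)
    def test_rotation_invariance(self, shift):
        angles = np.mod(np.deg2rad([10, 100, 190, 280]) + shift, 2 * np.pi)
        assert ps.count_symmetry(angles) == 4

    def test_fourier_tie_breaks_to_lower_mode(self):
        # two antipodal sites: every even mode has equal power; expect 2
        assert dominant_fourier_mode(np.array([0.0, np.pi])) == 2

    def test_azimuthal_groups_collapse_fragments(self):
        angles = np.deg2rad([0, 3, 6, 120, 123, 240])
        groups = azimuthal_groups(angles, r_ref=10.0, arc_threshold=5.0)
        assert len(groups) == 3


class TestClassification:
    @staticmethod
    def traj(records, sites=None, n_gen=1):
        class _T:
            pass

        t = _T()
        t.records = records
        t.final_sites = sites or []
        t.n_generations = n_gen
        return t

    @staticmethod
    def rec(angle_deg, T=10, gen=0, z=6.0):
        a = np.deg2rad(angle_deg)
        pos = np.array([20 + 10 * np.cos(a), 20 + 10 * np.sin(a), z])
        return ps.PrimordiumRecord(pos, T, float(np.mod(a, 2 * np.pi)), gen)

    def test_empty_trajectory_is_none(self):
        call = ps.classify_pattern(self.traj([]))
        assert call.label == "none" and call.fold == 0

    def test_simultaneous_uniform_ring_is_whorled(self):
        records = [self.rec(a, T=10) for a in (5, 95, 185, 275)]
        call = ps.classify_pattern(self.traj(records))
        assert call.label == "whorled" and call.fold == 4

    def test_staggered_consistent_offsets_are_spiral(self):
        records = [self.rec(np.mod(137.5 * i, 360), T=10 + 30 * i, gen=i)
                   for i in range(6)]
        call = ps.classify_pattern(self.traj(records, n_gen=6))
        assert call.label == "spiral"

    def test_meridional_stripes_are_ribbed(self):
        sites = []
        for i in range(6):
            a = np.deg2rad(60 * i)
            pos = np.array([20 + 10 * np.cos(a), 20 + 10 * np.sin(a), 8.0])
            sites.append(CandidateSite(pos, float(a), 8.0, 0.5, 30,
                                       meridional_extent=9.0,
                                       azimuthal_extent=2.0))
        call = ps.classify_pattern(self.traj([], sites=sites))
        assert call.label == "ribbed" and call.fold == 6

    def test_staggered_inconsistent_offsets_are_aberrant(self):
        angles = (0, 150, 30, 250, 90)
        records = [self.rec(a, T=10 + 30 * i, gen=i)
                   for i, a in enumerate(angles)]
        call = ps.classify_pattern(self.traj(records, n_gen=5))
        assert call.label == "aberrant"
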