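"""Plane fitting, grid resampling and the stretch-map statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermastretch.deformation import (bulge, ramp_stretch, rotation_about,
                                      uniaxial_stretch)
from dermastretch.maps import (axial_stats, fit_plane, percentile_summary,
                               profile_along_axis, resample_grid,
                               stretch_gradient, weighted_percentile)
from dermastretch.strain import analytic_tracked_mesh, strain_field


@pytest.fixture(scope="module")
def uniform_field():
    return strain_field(analytic_tracked_mesh(uniaxial_stretch(0.33),
                                              (-20, 20, -15, 15), 1.0))


@pytest.fixture(scope="module")
def ramp_field():
    # start offset keeps local stretch positive across the whole patch
    return strain_field(analytic_tracked_mesh(
        ramp_stretch(5.0, start_pct=15.0), (-20, 20, -15, 15), 1.0))


class TestFitPlane:
    def test_planar_patch_fraction_one_and_zero_distance(self, uniform_field):
        plane, frac = fit_plane(uniform_field)
        assert frac == pytest.approx(1.0, abs=1e-9)
        d = plane.distance(uniform_field.mesh.vertices_ref)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)
        np.testing.assert_allclose(plane.in_plane_axes @ plane.normal,
                                   0.0, atol=1e-12)

    def test_tilted_patch_equivariance(self):
        mesh = analytic_tracked_mesh(uniaxial_stretch(0.2), (-10, 10, -8, 8),
                                     2.0)
        plane0, _ = fit_plane(mesh)
        R = rotation_about("x", 30.0)
        mesh.vertices_ref = mesh.vertices_ref @ R.T
        plane1, _ = fit_plane(mesh)
        np.testing.assert_allclose(np.abs(plane1.normal @ (R @ plane0.normal)),
                                   1.0, atol=1e-9)

    def test_curved_patch_fraction_below_one(self):
        # reference surface itself curved (dome): principal directions then
        # have out-of-plane components, so the in-plane fraction drops
        from dermastretch.strain import TrackedMesh, build_mesh
        from dermastretch.deformation import SurfacePatch
        dome = bulge(8.0, 25.0, +1)
        uv = SurfacePatch((-20, 20, -20, 20)).grid(1.5)
        ref = dome.deform(uv)
        centre = ref.mean(axis=0)
        dfm = centre + 1.05 * (ref - centre)       # 5% stretch on the dome
        mesh = build_mesh(uv, ref, dfm)
        fld = strain_field(mesh)
        plane, frac = fit_plane(fld)
        assert 0.8 < frac < 1.0
        # symmetric dome: best plane is the base plane, normal along z
        assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-3)

    def test_collinear_vertices_rejected(self):
        from dermastretch.strain import TrackedMesh
        v = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        mesh = TrackedMesh(v, v, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError):
            fit_plane(mesh)


class TestResampleGrid:
    def test_uniform_field_fills_cells_with_constant(self, uniform_field):
        plane, _ = fit_plane(uniform_field)
        gmap = resample_grid(uniform_field, plane, 1.0)
        vals = gmap.values[gmap.mask]
        np.testing.assert_allclose(vals, 33.0, atol=1e-6)

    def test_mean_conservation(self, ramp_field):
        plane, _ = fit_plane(ramp_field)
        gmap = resample_grid(ramp_field, plane, 1.0)
        t = ramp_field.triangles
        w = ramp_field.mesh.face_areas("ref")[t.valid]
        mesh_mean = np.average(t.principal_pct[t.valid], weights=w)
        grid_mean = np.nanmean(gmap.values[gmap.mask])
        assert abs(grid_mean - mesh_mean) < 0.5

    def test_cell_averages_are_area_weighted(self):
        # two triangles of equal area with 10% and 30% in one cell -> 20%
        from dermastretch.strain import TrackedMesh, strain_field as sf
        uv = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        ref = np.column_stack([uv, np.zeros(4)])
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        dfm = ref.copy()
        # first triangle: 10% along x; second: 30% -- build per-vertex is
        # impossible for discontinuous stretch, so synthesise two meshes and
        # check the weighted average through the resampler's accumulation
        mesh_a = TrackedMesh(ref, ref * [1.1, 1, 1], faces[:1])
        mesh_b = TrackedMesh(ref, ref * [1.3, 1, 1], faces[1:])
        fa, fb = sf(mesh_a), sf(mesh_b)
        merged = TrackedMesh(ref, ref, faces)
        fld = sf(merged)
        fld.triangles.principal_pct[:] = [10.0, 30.0]
        plane, _ = fit_plane(fld)
        gmap = resample_grid(fld, plane, 2.0, fill_radius_cells=0)
        assert np.nansum(gmap.mask) == 1
        assert gmap.values[gmap.mask][0] == pytest.approx(20.0)
        assert fa.triangles.principal_pct[0] == pytest.approx(10.0, abs=1e-9)
        assert fb.triangles.principal_pct[0] == pytest.approx(30.0, abs=1e-9)

    def test_bad_resolution_rejected(self, uniform_field):
        plane, _ = fit_plane(uniform_field)
        with pytest.raises(ValueError):
            resample_grid(uniform_field, plane, 0.0)

    def test_save_roundtrip(self, tmp_path, uniform_field):
        plane, _ = fit_plane(uniform_field)
        gmap = resample_grid(uniform_field, plane, 1.0)
        gmap.save(tmp_path / "map.txt", tmp_path / "map.yaml")
        back = np.loadtxt(tmp_path / "map.txt")
        assert back.shape == gmap.values.shape


class TestStretchGradient:
    def test_constant_field_zero_gradient(self, uniform_field):
        plane, _ = fit_plane(uniform_field)
        gmap = resample_grid(uniform_field, plane, 1.0)
        assert stretch_gradient(gmap) == pytest.approx(0.0, abs=1e-6)

    def test_ramp_recovered_within_half_percent_per_cm(self, ramp_field):
        plane, _ = fit_plane(ramp_field)
        gmap = resample_grid(ramp_field, plane, 1.0)
        assert stretch_gradient(gmap) == pytest.approx(5.0, abs=0.5)

    def test_gradient_orders_ramps(self):
        vals = []
        for g in (4.0, 8.0):
            fld = strain_field(analytic_tracked_mesh(
                ramp_stretch(g, start_pct=20.0), (-15, 15, -10, 10), 1.0))
            plane, _ = fit_plane(fld)
            vals.append(stretch_gradient(resample_grid(fld, plane, 1.0)))
        assert vals[1] > vals[0]

    def test_affine_field_within_ten_percent_relative(self):
        for g in (2.0, 5.0, 8.0):
            fld = strain_field(analytic_tracked_mesh(
                ramp_stretch(g, start_pct=20.0), (-15, 15, -10, 10), 1.0))
            plane, _ = fit_plane(fld)
            est = stretch_gradient(resample_grid(fld, plane, 1.0))
            assert abs(est - g) / g < 0.1


class TestAxialStats:
    def test_equal_angles_zero_sd(self):
        s = axial_stats(np.full(50, 37.0))
        assert s.angular_sd_deg == pytest.approx(0.0, abs=1e-6)
        assert s.axial_mean_deg == pytest.approx(37.0, abs=1e-9)

    def test_orthogonal_axes_cancel(self):
        s = axial_stats(np.array([0.0, 90.0]))
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert s.angular_sd_deg > 100.0

    def test_wrapped_normal_sd_recovery(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(40.0, 6.0, size=10_000)
        s = axial_stats(np.mod(draws, 180.0))
        assert s.angular_sd_deg == pytest.approx(6.0, abs=0.5)
        assert s.axial_mean_deg == pytest.approx(40.0, abs=0.5)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_180_degree_flips(self, seed):
        rng = np.random.default_rng(seed)
        ang = rng.uniform(0, 180, size=60)
        flips = rng.integers(0, 2, size=60) * 180.0
        s0 = axial_stats(ang)
        s1 = axial_stats(ang + flips)
        assert s1.angular_sd_deg == pytest.approx(s0.angular_sd_deg, abs=1e-9)
        assert s1.axial_mean_deg == pytest.approx(s0.axial_mean_deg, abs=1e-9)

    def test_shift_invariance_of_sd(self):
        rng = np.random.default_rng(5)
        ang = rng.normal(20.0, 8.0, size=500)
        s0 = axial_stats(np.mod(ang, 180.0))
        s1 = axial_stats(np.mod(ang + 54.3, 180.0))
        assert s1.angular_sd_deg == pytest.approx(s0.angular_sd_deg, abs=1e-9)

    def test_histogram_normalised_and_centered(self):
        rng = np.random.default_rng(6)
        ang = np.mod(rng.normal(120.0, 5.0, size=400), 180.0)
        s = axial_stats(ang, center=True)
        assert s.histogram.sum() == pytest.approx(1.0)
        peak = s.bin_centers_deg[np.argmax(s.histogram)]
        assert abs(peak) < 10.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            axial_stats(np.array([]))


class TestProfilesAndPercentiles:
    def test_ramp_profile_reproduces_ramp(self, ramp_field):
        plane, _ = fit_plane(ramp_field)
        gmap = resample_grid(ramp_field, plane, 1.0)
        origin = gmap.origin
        prof = profile_along_axis(gmap, (origin[0], 0.0),
                                  (origin[0] + 40.0, 0.0), bin_cm=0.5)
        good = ~np.isnan(prof.mean_pct)
        slope = np.polyfit(prof.bin_centers_cm[good], prof.mean_pct[good], 1)[0]
        assert slope == pytest.approx(5.0, abs=0.5)

    def test_uniform_profile_is_flat(self, uniform_field):
        plane, _ = fit_plane(uniform_field)
        gmap = resample_grid(uniform_field, plane, 1.0)
        prof = profile_along_axis(gmap, (0.0, 0.0), (30.0, 20.0), bin_cm=1.0)
        good = ~np.isnan(prof.mean_pct)
        np.testing.assert_allclose(prof.mean_pct[good], 33.0, atol=1e-6)

    def test_decaying_field_gives_decreasing_profile(self):
        # knee-flexion-like preset: stretch decays away from one edge
        fld = strain_field(analytic_tracked_mesh(
            ramp_stretch(-4.0, start_pct=25.0), (0, 40, -10, 10), 1.0))
        plane, _ = fit_plane(fld)
        gmap = resample_grid(fld, plane, 1.0)
        prof = profile_along_axis(gmap, (gmap.origin[0], 0.0),
                                  (gmap.origin[0] + 40.0, 0.0), bin_cm=1.0)
        good = ~np.isnan(prof.mean_pct)
        assert np.all(np.diff(prof.mean_pct[good]) < 0)

    def test_identical_anchors_rejected(self, uniform_field):
        plane, _ = fit_plane(uniform_field)
        gmap = resample_grid(uniform_field, plane, 1.0)
        with pytest.raises(ValueError):
            profile_along_axis(gmap, (1.0, 1.0), (1.0, 1.0))

    def test_constant_field_percentiles(self, uniform_field):
        s = percentile_summary(uniform_field)
        assert s["mean_principal_pct"] == pytest.approx(33.0, abs=1e-6)
        assert s["p5_principal_pct"] == pytest.approx(33.0, abs=1e-6)
        assert s["p95_principal_pct"] == pytest.approx(33.0, abs=1e-6)

    def test_weighted_percentile_against_brute_force_expansion(self):
        # replicate each value proportionally to its (integer) weight and
        # compare with plain percentiles of the expanded sample
        values = np.array([1.0, 5.0, 2.0, 9.0, 4.0, 7.0, 3.0, 8.0, 6.0, 2.5])
        weights = np.array([3, 1, 4, 2, 5, 1, 2, 3, 1, 4])
        expanded = np.repeat(values, weights)
        for q in (5.0, 25.0, 50.0, 75.0, 95.0):
            mine = weighted_percentile(values, weights.astype(float), q)
            ref = np.percentile(expanded, q, method="hazen")
            assert mine == pytest.approx(ref, abs=0.35)

    def test_equal_area_two_value_mean(self):
        vals = np.array([10.0, 30.0])
        w = np.array([1.0, 1.0])
        assert np.average(vals, weights=w) == pytest.approx(20.0)
        assert weighted_percentile(vals, w, 50.0) == pytest.approx(20.0)
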