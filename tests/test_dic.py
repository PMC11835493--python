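"""Digital image correlation: integer ZNCC matching against a brute-force
oracle, subpixel refinement against known warps, and pose-chain tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from dermastretch import dic
from dermastretch.speckle import SpeckleParams, generate_speckle


@pytest.fixture(scope="module")
def texture():
    return generate_speckle(SpeckleParams(canvas_size=(24.0, 20.0),
                                          raster_scale=5.0, seed=9)).image


def shift_image(img, dx, dy):
    """Integer roll; keeps content identical for exact-match tests."""
    return np.roll(np.roll(img, dy, axis=0), dx, axis=1)


def brute_force_zncc_field(ref, target, grid, search):
    """Independent exhaustive ZNCC argmax per subset (the oracle).

    Plain nested loops over every candidate displacement; ties resolved
    toward the smallest displacement magnitude, then lexicographic (dx, dy).
    """
    r = grid.radius
    th, tw = target.shape
    out = np.full((len(grid), 2), np.nan)
    scores = np.zeros(len(grid))
    for i, (cx, cy) in enumerate(grid.centers):
        f = ref[cy - r: cy + r + 1, cx - r: cx + r + 1].astype(float)
        fc = f - f.mean()
        fn = np.sqrt((fc**2).sum())
        best = None
        for dy in range(-search, search + 1):
            for dx in range(-search, search + 1):
                x, y = cx + dx, cy + dy
                if x - r < 0 or y - r < 0 or x + r + 1 > tw or y + r + 1 > th:
                    continue
                g = target[y - r: y + r + 1, x - r: x + r + 1].astype(float)
                gc = g - g.mean()
                gn = np.sqrt((gc**2).sum())
                score = (fc * gc).sum() / (fn * gn) if fn * gn > 0 else 0.0
                key = (-round(score, 9), np.hypot(dx, dy), dx, dy)
                if best is None or key < best[0]:
                    best = (key, dx, dy, score)
        out[i] = (cx + best[1], cy + best[2])
        scores[i] = best[3]
    return out, scores


class TestIntegerMatching:
    def test_pure_integer_shift_recovered_exactly(self, texture):
        target = shift_image(texture, 7, -3)
        grid = dic.SubsetGrid.regular(texture.shape, 10, 10, margin=25)
        f = dic.match_integer(texture, target, grid, search_radius=10)
        assert f.matched.all()
        np.testing.assert_array_equal(f.displacements,
                                      np.tile([7, -3], (len(grid), 1)))
        np.testing.assert_allclose(f.scores, 1.0, atol=1e-9)

    def test_identity_gives_zero_displacement_score_one(self, texture):
        grid = dic.SubsetGrid.regular(texture.shape, 10, 10, margin=16)
        f = dic.match_integer(texture, texture, grid, search_radius=5)
        np.testing.assert_array_equal(f.displacements, 0.0)
        np.testing.assert_allclose(f.scores, 1.0, atol=1e-12)

    def test_agrees_with_brute_force_oracle_on_small_images(self, texture):
        # exact argmax agreement (including tie-breaks) on a <= 128 x 128 pair
        ref = texture[:100, :120]
        rng = np.random.default_rng(4)
        target = np.clip(ref * 0.9 + 0.03
                         + rng.normal(0, 0.02, ref.shape), 0, 1)
        target = shift_image(target, 3, 2)
        grid = dic.SubsetGrid.regular(ref.shape, 8, 8, margin=20)
        search = 6
        f = dic.match_integer(ref, target, grid, search)
        oracle_pts, oracle_scores = brute_force_zncc_field(ref, target, grid,
                                                           search)
        np.testing.assert_array_equal(f.target_points, oracle_pts)
        np.testing.assert_allclose(f.scores, oracle_scores, atol=1e-6)

    def test_flat_subset_flagged_low_score(self):
        ref = np.full((80, 80), 0.5)
        rng = np.random.default_rng(0)
        target = rng.uniform(size=(80, 80))
        grid = dic.SubsetGrid(np.array([[40, 40]]), radius=10, spacing=5)
        f = dic.match_integer(ref, target, grid, search_radius=5)
        assert f.status[0] == dic.STATUS_LOW_SCORE
        assert f.scores[0] == 0.0

    def test_out_of_bounds_flagged(self, texture):
        grid = dic.SubsetGrid(np.array([[2, 2]]), radius=10, spacing=5)
        f = dic.match_integer(texture, texture, grid, search_radius=5)
        assert f.status[0] == dic.STATUS_OUT_OF_BOUNDS

    @settings(max_examples=10, deadline=None)
    @given(dx=st.integers(-6, 6), dy=st.integers(-6, 6))
    def test_shift_equivariance(self, texture, dx, dy):
        grid = dic.SubsetGrid.regular(texture.shape, 10, 10, margin=20)
        base = dic.match_integer(texture, texture, grid, search_radius=8)
        shifted = dic.match_integer(texture, shift_image(texture, dx, dy),
                                    grid, search_radius=8)
        np.testing.assert_array_equal(
            shifted.displacements[shifted.matched] -
            base.displacements[shifted.matched],
            np.tile([dx, dy], (int(shifted.matched.sum()), 1)))

    def test_photometric_invariance(self, texture):
        # affine intensity change of the target leaves ZNCC matches unchanged
        grid = dic.SubsetGrid.regular(texture.shape, 10, 10, margin=22)
        target = shift_image(texture, 4, 1)
        f0 = dic.match_integer(texture, target, grid, search_radius=6)
        f1 = dic.match_integer(texture, 0.6 * target + 0.25, grid,
                               search_radius=6)
        np.testing.assert_array_equal(f0.target_points, f1.target_points)
        np.testing.assert_allclose(f0.scores, f1.scores, atol=1e-9)


class TestSubpixelRefinement:
    def test_subpixel_translation_recovered(self, texture):
        true = (0.5, -0.25)
        target = ndimage.shift(texture, (true[1], true[0]), order=3,
                               mode="nearest")
        grid = dic.SubsetGrid.regular(texture.shape, 12, 12, margin=20)
        f = dic.match_integer(texture, target, grid, search_radius=4)
        f = dic.refine_subpixel(f, texture, target)
        d = f.displacements[f.matched]
        assert np.abs(d - np.array(true)).max() < 0.05

    def test_quadratic_mode_alone_is_coarser_but_close(self, texture):
        target = ndimage.shift(texture, (0.0, 0.5), order=3, mode="nearest")
        grid = dic.SubsetGrid.regular(texture.shape, 12, 12, margin=20)
        f = dic.match_integer(texture, target, grid, search_radius=4)
        f = dic.refine_subpixel(f, texture, target, mode="quadratic")
        d = f.displacements[f.matched]
        assert np.abs(d[:, 0] - 0.5).mean() < 0.15

    def test_affine_warp_residual_under_tenth_pixel(self, texture):
        # 10% uniaxial image stretch about the centre: first-order subset
        # shape function must absorb it
        h, w = texture.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        cx, cy = w / 2, h / 2
        src_x = cx + (xx - cx) / 1.1
        target = ndimage.map_coordinates(texture, [yy, src_x], order=3,
                                         mode="nearest")
        grid = dic.SubsetGrid.regular(texture.shape, 12, 12, margin=22)
        f = dic.match_integer(texture, target, grid, search_radius=8)
        f = dic.refine_subpixel(f, texture, target)
        ok = f.matched
        expected = (grid.centers[ok, 0] - cx) * 0.1
        err = f.displacements[ok, 0] - expected
        assert np.abs(err).mean() < 0.1

    def test_noop_on_already_perfect_match(self, texture):
        grid = dic.SubsetGrid.regular(texture.shape, 10, 10, margin=16)
        f0 = dic.match_integer(texture, texture, grid, search_radius=3)
        f1 = dic.refine_subpixel(f0, texture, texture)
        np.testing.assert_allclose(f1.target_points[f1.matched],
                                   f0.target_points[f1.matched], atol=1e-3)

    def test_displacement_field_rms_under_tenth_pixel(self, texture):
        # smooth sinusoidal warp: RMS error at subset centres < 0.1 px
        h, w = texture.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        disp = 1.5 * np.sin(2 * np.pi * xx / w)
        target = ndimage.map_coordinates(texture, [yy, xx - disp], order=3,
                                         mode="nearest")
        grid = dic.SubsetGrid.regular(texture.shape, 10, 10, margin=20)
        f = dic.match_integer(texture, target, grid, search_radius=4)
        f = dic.refine_subpixel(f, texture, target)
        ok = f.matched
        expected = 1.5 * np.sin(2 * np.pi * grid.centers[ok, 0] / w)
        rms = np.sqrt(np.mean((f.displacements[ok, 0] - expected) ** 2))
        assert rms < 0.1


class TestPoseChain:
    def test_smudge_flags_local_tracks_only(self, texture):
        # a blurred stripe (smudged ink) kills matches inside it, not outside
        target = texture.copy()
        target[:, 50:70] = ndimage.gaussian_filter(target[:, 50:70], 6.0)
        grid = dic.SubsetGrid.regular(texture.shape, 8, 8, margin=18)
        f = dic.match_integer(texture, target, grid, search_radius=4)
        f = dic.refine_subpixel(f, texture, target)
        inside = (grid.centers[:, 0] > 52) & (grid.centers[:, 0] < 68)
        outside = (grid.centers[:, 0] < 35) | (grid.centers[:, 0] > 85)
        assert (f.status[inside] != dic.STATUS_MATCHED).mean() > 0.5
        assert (f.status[outside] == dic.STATUS_MATCHED).mean() > 0.95

    def test_identity_chain_returns_reference_coordinates(
            self, small_identity_run):
        chain = small_identity_run.chain
        ok = chain.ok
        np.testing.assert_allclose(chain.px_def_a[ok], chain.px_ref_a[ok],
                                   atol=0.1)

    def test_stretch_chain_keeps_most_tracks(self, small_stretch_run):
        assert small_stretch_run.chain.ok.mean() > 0.8

    def test_failure_when_images_unrelated(self):
        a = generate_speckle(SpeckleParams(canvas_size=(20, 16),
                                           raster_scale=5.0, seed=1)).image
        b = generate_speckle(SpeckleParams(canvas_size=(20, 16),
                                           raster_scale=5.0, seed=2)).image
        grid = dic.SubsetGrid.regular(a.shape, 8, 8, margin=18)
        with pytest.raises(dic.MatchingFailure):
            dic.track_pose_chain([a, a], [b, b], grid)


def test_matchfield_csv_roundtrip(tmp_path, texture):
    grid = dic.SubsetGrid.regular(texture.shape, 10, 10, margin=16)
    f = dic.match_integer(texture, shift_image(texture, 2, 1), grid,
                          search_radius=4, pairing="camA-camB@ref")
    path = tmp_path / "matches.csv"
    f.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert list(df.columns) == ["ref_x", "ref_y", "tgt_x", "tgt_y",
                                "score", "status", "pairing"]
    assert len(df) == len(grid)
    assert (df["pairing"] == "camA-camB@ref").all()


def test_grid_requires_overlapping_subsets():
    with pytest.raises(ValueError):
        dic.SubsetGrid(np.array([[50, 50]]), radius=4, spacing=8)
    with pytest.raises(ValueError):
        dic.SubsetGrid(np.array([[50, 50]]), radius=8, spacing=0)
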