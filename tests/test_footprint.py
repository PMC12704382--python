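"""Time projection, top-p% accumulation mask, roundness, width, curvature."""

import numpy as np
import pytest

import tipflux as tf
from tipflux.footprint import NoContrastError, TimeProjection

from conftest import SMALL_ACQ, truth_track


def small_config(**kwargs) -> tf.SyntheticMovieConfig:
    return tf.SyntheticMovieConfig(acquisition=SMALL_ACQ, **kwargs)


def render_cap_frame(radius_um, px=0.1356, H=224, W=295, tip_x=180.0):
    """Noise-free tube + hemispherical cap test frame; returns frame and tip."""
    R = radius_um / px
    y0 = (H - 1) / 2.0
    cx = tip_x - R
    yy, xx = np.mgrid[0:H, 0:W]
    inside = ((xx <= cx) & (np.abs(yy - y0) <= R)) | ((xx - cx) ** 2 + (yy - y0) ** 2 <= R**2)
    return np.where(inside, 160.0, 100.0), np.array([tip_x, y0])


class TestTimeProject:
    def test_single_frame_projection_is_frame(self):
        frame = np.random.default_rng(0).random((9, 9))
        proj = tf.time_project(frame[None])
        np.testing.assert_array_equal(proj.pixels, frame)

    def test_two_frame_mean(self):
        a, b = np.ones((4, 4)), np.full((4, 4), 3.0)
        proj = tf.time_project(np.stack([a, b]))
        np.testing.assert_allclose(proj.pixels, 2.0)

    def test_masked_values_excluded_with_counts(self):
        stack = np.array([[[1.0, np.nan]], [[3.0, 4.0]]])
        proj = tf.time_project(stack)
        np.testing.assert_allclose(proj.pixels, [[2.0, 4.0]])
        np.testing.assert_array_equal(proj.counts, [[2, 1]])

    def test_crescent_projection_wider_than_single_frame(self):
        """The wandering spot paints an arc over time: the bright footprint of
        the projection spans more pixels than any single frame's spot."""
        level = 190.0  # above cytosol, inside the spot's detectable halo
        for seed in (4, 5, 6):
            sm = tf.generate_movie(small_config(regime="crescent", seed=seed))
            cropped = tf.crop_to_track(sm.movie, truth_track(sm))
            proj = tf.time_project(cropped)
            proj_area = (proj.pixels > level).sum()
            frame_area = (cropped.pixels > level).sum(axis=(1, 2)).max()
            assert proj_area > 1.1 * frame_area


class TestTopFractionMask:
    def test_order_statistics_oracle(self):
        """113 = ceil(4.5% of 2500) pixels retained when all values differ."""
        rng = np.random.default_rng(3)
        img = rng.permutation(2500).reshape(50, 50).astype(float)
        region = tf.top_fraction_mask(TimeProjection(img, np.ones((50, 50), int), 0.1356))
        assert region.mask.sum() == int(np.ceil(0.045 * 2500))
        assert region.area_um2 == pytest.approx(113 * 0.0184, abs=0.01)
        # oracle: exhaustive sort
        assert set(img[region.mask]) == set(np.sort(img.ravel())[-113:])

    def test_full_percentage_selects_everything(self):
        img = np.arange(36.0).reshape(6, 6)
        region = tf.top_fraction_mask(TimeProjection(img, np.ones((6, 6), int), 1.0), p_percent=100)
        assert region.mask.all()

    def test_no_contrast_rejected(self):
        flat = TimeProjection(np.ones((5, 5)), np.ones((5, 5), int), 1.0)
        with pytest.raises(NoContrastError):
            tf.top_fraction_mask(flat)

    def test_mask_monotone_in_p(self):
        rng = np.random.default_rng(1)
        img = TimeProjection(rng.random((40, 40)), np.ones((40, 40), int), 1.0)
        small = tf.top_fraction_mask(img, p_percent=2.0).mask
        large = tf.top_fraction_mask(img, p_percent=10.0).mask
        assert (small <= large).all()

    def test_histogram_threshold_emulation(self):
        """256-bin histogram thresholding of an integer image retains ~p% of
        pixels, within one histogram bin of the exact percentile."""
        rng = np.random.default_rng(5)
        img = rng.integers(0, 4096, (50, 50)).astype(float)
        proj = TimeProjection(img, np.ones((50, 50), int), 1.0)
        exact = tf.top_fraction_mask(proj)
        binned = tf.top_fraction_mask(proj, histogram_bins=256)
        frac = binned.mask.mean()
        assert frac == pytest.approx(0.045, abs=0.01)
        assert abs(binned.threshold - exact.threshold) <= (img.max() - img.min()) / 256

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.random((30, 30))
        a = tf.top_fraction_mask(TimeProjection(img, np.ones_like(img, int), 1.0))
        b = tf.top_fraction_mask(TimeProjection(3.0 * img + 17.0, np.ones_like(img, int), 1.0))
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.roundness == b.roundness


class TestRoundness:
    def test_disc_is_round(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disc = (xx - 20) ** 2 + (yy - 20) ** 2 <= 10**2
        assert tf.measure_roundness(disc) == pytest.approx(1.0, abs=0.05)

    def test_two_to_one_ellipse(self):
        """Roundness 4A/(pi a^2) of a 2:1 ellipse equals b/a = 0.5."""
        yy, xx = np.mgrid[0:101, 0:101]
        ellipse = ((xx - 50) / 40.0) ** 2 + ((yy - 50) / 20.0) ** 2 <= 1.0
        assert tf.measure_roundness(ellipse) == pytest.approx(0.5, abs=0.05)

    def test_fragmented_mask_uses_largest_component(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True  # 100-px square
        mask[25, 25] = True  # stray pixel
        square_only = np.zeros_like(mask)
        square_only[5:15, 5:15] = True
        assert tf.measure_roundness(mask) == tf.measure_roundness(square_only)

    def test_spheroid_rounder_than_crescent(self):
        """Cohort-level shape discrimination: stable-spot projections are
        rounder than wandering-spot projections."""
        rounds = {"spitzenkoerper": [], "crescent": []}
        for i, regime in enumerate(rounds) :
            for seed in (21, 22):
                sm = tf.generate_movie(small_config(regime=regime, seed=seed + i))
                thr = tf.extracellular_threshold(sm.movie)
                cropped = tf.crop_to_track(tf.apply_threshold(sm.movie, thr), truth_track(sm))
                region = tf.top_fraction_mask(tf.time_project(cropped))
                rounds[regime].append(region.roundness)
        assert min(rounds["spitzenkoerper"]) > max(rounds["crescent"])


class TestWidth:
    def test_synthetic_tube_width(self):
        frame, tip = render_cap_frame(1.25)
        width = tf.measure_width(frame, tip, (1, 0), 0.1356, 110.0)
        assert width == pytest.approx(2.5, abs=0.1356)

    def test_rotation_invariance(self):
        from scipy.ndimage import rotate

        frame, tip = render_cap_frame(1.25)
        rotated = rotate(frame, 30.0, reshape=False, order=1, cval=100.0)
        center = (np.array(frame.shape[::-1]) - 1) / 2.0
        angle = np.deg2rad(-30.0)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        tip_rot = rot @ (tip - center) + center
        width = tf.measure_width(rotated, tip_rot, tuple(rot @ [1, 0]), 0.1356, 110.0)
        assert width == pytest.approx(2.5, abs=2 * 0.1356)

    def test_width_independent_of_spot_intensity(self):
        frame, tip = render_cap_frame(1.25)
        bright = frame.copy()
        bright[108:116, 170:178] += 500.0  # apical spot
        w0 = tf.measure_width(frame, tip, (1, 0), 0.1356, 110.0)
        w1 = tf.measure_width(bright, tip, (1, 0), 0.1356, 110.0)
        assert w0 == w1


class TestCurvature:
    @pytest.mark.parametrize("radius_um", [1.0, 1.25, 1.5])
    def test_hemispherical_cap_curvature(self, radius_um):
        frame, tip = render_cap_frame(radius_um)
        k = tf.estimate_apex_curvature(frame, tip, (1, 0), 0.1356, 110.0)
        assert k == pytest.approx(1.0 / radius_um, rel=0.10)

    def test_flat_edge_near_zero(self):
        frame = np.full((224, 295), 100.0)
        frame[:, :180] = 160.0  # flat vertical front
        k = tf.estimate_apex_curvature(frame, (179.0, 111.5), (1, 0), 0.1356, 110.0)
        assert abs(k) < 0.05

    def test_invariant_to_intensity_scaling(self):
        frame, tip = render_cap_frame(1.25)
        k0 = tf.estimate_apex_curvature(frame, tip, (1, 0), 0.1356, 110.0)
        k1 = tf.estimate_apex_curvature(frame * 10.0, tip, (1, 0), 0.1356, 1100.0)
        assert k0 == pytest.approx(k1, rel=1e-9)
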