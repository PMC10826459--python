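"""Quantification pipeline tests on constructed and generated stacks."""

import numpy as np
import pytest

from spheroflow import imaging as im
from spheroflow.imaging import ROIMask, TimeLapseStack


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(xx - center[0], yy - center[1]) <= radius


def make_stack(frames, **kwargs):
    defaults = dict(pixel_size=1.0, frame_interval=1.0)
    defaults.update(kwargs)
    return TimeLapseStack(channels={"gfp": np.asarray(frames, float)}, **defaults)


class TestSegmentation:
    def test_synthetic_disk_radius_recovered_within_3pct(self):
        img = np.full((160, 160), 10.0)
        img[disk_mask((160, 160), (80, 80), 50)] = 100.0
        roi = im.segment_spheroid(img, polarity="bright")
        assert roi.equivalent_radius == pytest.approx(50, rel=0.03)
        assert roi.centroid == pytest.approx((80, 80), abs=1.0)

    def test_dark_object_polarity(self):
        img = np.full((120, 120), 200.0)
        img[disk_mask((120, 120), (60, 60), 30)] = 20.0
        roi = im.segment_spheroid(img, polarity="dark")
        assert roi.equivalent_radius == pytest.approx(30, rel=0.05)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            im.segment_spheroid(np.zeros((50, 50)))

    def test_user_mask_passed_through(self):
        mask = disk_mask((64, 64), (32, 32), 10)
        roi = im.segment_spheroid(np.zeros((64, 64)), method="provided-mask", mask=mask)
        assert np.array_equal(roi.mask, mask)

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((64, 64), bool)
        mask[5, 5] = mask[50, 50] = True
        with pytest.raises(ValueError):
            ROIMask(mask=mask)


class TestIntensitySeries:
    def test_normalization_is_ratio_to_first_frame(self):
        mask = disk_mask((40, 40), (20, 20), 8)
        frames = np.stack([mask * v for v in (100.0, 150.0, 200.0)])
        stack = make_stack(frames)
        roi = ROIMask(mask=mask)
        series = im.intensity_timeseries(stack, roi, "gfp", background=None)
        assert np.allclose(series.normalized, [1.0, 1.5, 2.0])
        area = mask.sum()
        assert np.allclose(series.raw_density, [100 * area, 150 * area, 200 * area])

    def test_constant_stack_normalizes_to_one(self):
        mask = disk_mask((40, 40), (20, 20), 8)
        stack = make_stack(np.stack([mask * 7.0] * 5))
        series = im.intensity_timeseries(stack, ROIMask(mask=mask), "gfp", background=None)
        assert np.allclose(series.normalized, 1.0)

    def test_background_subtraction_removes_uniform_offset(self):
        mask = disk_mask((80, 80), (40, 40), 10)
        frames = np.stack([mask * 50.0 + off for off in (10.0, 30.0, 20.0)])
        series = im.intensity_timeseries(make_stack(frames), ROIMask(mask=mask), "gfp")
        assert np.allclose(series.normalized, 1.0, atol=1e-9)

    def test_zero_baseline_rejected(self):
        mask = disk_mask((40, 40), (20, 20), 8)
        frames = np.stack([mask * 0.0, mask * 1.0])
        with pytest.raises(ValueError):
            im.intensity_timeseries(make_stack(frames), ROIMask(mask=mask), "gfp",
                                    background=None)


class TestPolarTransform:
    def test_rotationally_symmetric_spot_is_flat_in_theta(self):
        yy, xx = np.mgrid[0:101, 0:101]
        img = np.exp(-((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * 15**2))
        pol = im.polar_transform(img, (50, 50), r_max=40)
        cv = pol.std(axis=1) / pol.mean(axis=1)
        assert cv.max() < 0.01

    def test_90_degree_rotation_shifts_theta_by_90(self):
        rng = np.random.default_rng(0)
        base = rng.random((30, 30))
        from scipy.ndimage import zoom

        img = zoom(base, 101 / 30, order=1)[:101, :101]
        rot = np.rot90(img)  # counterclockwise rotation by 90 deg
        pol = im.polar_transform(img, (50, 50), r_max=40, n_theta=360)
        pol_rot = im.polar_transform(rot, (50, 50), r_max=40, n_theta=360)
        shifted = np.roll(pol, 90, axis=1)
        c = np.corrcoef(shifted.ravel(), pol_rot.ravel())[0, 1]
        assert c > 0.99

    def test_single_bright_pixel_maps_to_expected_r_theta(self):
        img = np.zeros((101, 101))
        img[50 - 30, 50] = 1.0  # 30 px straight above center -> theta 90
        pol = im.polar_transform(img, (50, 50), r_max=45, n_theta=360)
        ir, it = np.unravel_index(np.argmax(pol), pol.shape)
        r = (ir + 0.5) * 45 / pol.shape[0]
        theta = (it + 0.5) * 360 / 360
        assert r == pytest.approx(30, abs=1.0)
        assert theta == pytest.approx(90, abs=1.5)

    def test_flux_preserved_within_2pct(self):
        yy, xx = np.mgrid[0:101, 0:101]
        img = np.exp(-((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * 12**2)) + 0.1
        r_max = 40
        n_r = 200
        pol = im.polar_transform(img, (50, 50), r_max=r_max, n_r=n_r, n_theta=720)
        rs = (np.arange(n_r) + 0.5) * r_max / n_r
        dr = r_max / n_r
        dth = 2 * np.pi / 720
        polar_flux = (pol * rs[:, None] * dr * dth).sum()
        cart_flux = img[disk_mask(img.shape, (50, 50), r_max)].sum()
        assert polar_flux == pytest.approx(cart_flux, rel=0.02)

    def test_r_max_beyond_bounds_clipped_with_warning(self):
        img = np.ones((51, 51))
        with pytest.warns(UserWarning):
            im.polar_transform(img, (25, 25), r_max=100)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            im.polar_transform(np.ones((20, 20)), (100, 5), r_max=5)


class TestAzimuthalProfile:
    def test_axisymmetric_spheroid_gives_flat_profile(self):
        from spheroflow.synth import SyntheticConfig, render_timelapse

        cfg = SyntheticConfig(noise_gaussian=0.0, poisson_scale=0.0, seed=1,
                              n_frames=8, frame_interval=10.0)
        stack, truth = render_timelapse(cfg)
        roi = ROIMask(mask=truth.roi_mask)
        prof = im.azimuthal_profile(stack, roi, "gfp", background=None)
        for row in prof.values:
            assert row.max() / row.min() < 1.05

    def test_top_weighted_gradient_recovered(self):
        from spheroflow.synth import SyntheticConfig, render_timelapse

        cfg = SyntheticConfig(asymmetry=1.25, noise_gaussian=0.0, poisson_scale=0.0,
                              seed=2)
        stack, truth = render_timelapse(cfg)
        roi = ROIMask(mask=truth.roi_mask)
        prof = im.azimuthal_profile(stack, roi, "gfp", times=[0.0, 70.0],
                                    background=None)
        _, _, ratio = im.asymmetry_index(prof, 70.0)
        assert ratio == pytest.approx(1.25, rel=0.02)

    def test_t0_profile_mean_is_one(self, small_synth):
        _, stack, truth = small_synth
        roi = ROIMask(mask=truth.roi_mask)
        prof = im.azimuthal_profile(stack, roi, "gfp", times=[0.0, 70.0])
        assert prof.values[0].mean() == pytest.approx(1.0)

    def test_aggregation_of_identical_spheroids_has_zero_sd(self, small_synth):
        _, stack, truth = small_synth
        roi = ROIMask(mask=truth.roi_mask)
        prof = im.azimuthal_profile(stack, roi, "gfp", times=[0.0, 70.0])
        mean, sd = im.aggregate_profiles([prof, prof, prof])
        assert np.allclose(sd, 0.0)
        assert np.allclose(mean.values, prof.values)

    def test_missing_time_rejected(self, small_synth):
        _, stack, truth = small_synth
        roi = ROIMask(mask=truth.roi_mask)
        with pytest.raises(ValueError):
            im.azimuthal_profile(stack, roi, "gfp", times=[123.0])


class TestAsymmetryIndex:
    def make_profile(self, row):
        theta = np.arange(360.0)  # integer bin centers: 90 and 270 exact
        return im.AzimuthalProfile(theta=theta, times=np.array([0.0]),
                                   values=np.array([row]))

    def test_flat_profile_gives_unit_ratio(self):
        prof = self.make_profile(np.ones(360))
        top, bottom, ratio = im.asymmetry_index(prof, 0.0)
        assert (top, bottom, ratio) == (1.0, 1.0, 1.0)

    def test_printed_endpoint_values_give_expected_ratio(self):
        row = np.ones(360)
        row[90] = 12.3  # bin centered on theta = 90
        row[270] = 9.8
        prof = self.make_profile(row)
        _, _, ratio = im.asymmetry_index(prof, 0.0)
        assert ratio == pytest.approx(12.3 / 9.8, rel=1e-12)

    def test_mirrored_profile_inverts_ratio(self):
        rng = np.random.default_rng(3)
        row = 1 + rng.random(360)
        prof = self.make_profile(row)
        # theta -> -theta reflection (swaps top and bottom poles)
        mirrored = self.make_profile(np.roll(row[::-1], 1))
        r1 = im.asymmetry_index(prof, 0.0)[2]
        r2 = im.asymmetry_index(mirrored, 0.0)[2]
        assert r2 == pytest.approx(1.0 / r1, rel=1e-9)


class TestTemporalSD:
    def test_constant_stack_gives_zero_map(self):
        stack = TimeLapseStack(channels={"bf": np.full((5, 20, 20), 3.0)},
                               pixel_size=1.0, frame_interval=1.0)
        assert np.allclose(im.temporal_sd_map(stack, "bf").sd, 0.0)

    def test_alternating_pixel_has_population_sd_one(self):
        frames = np.zeros((4, 8, 8))
        frames[1, 3, 3] = frames[3, 3, 3] = 2.0
        stack = TimeLapseStack(channels={"bf": frames}, pixel_size=1.0,
                               frame_interval=1.0)
        sd = im.temporal_sd_map(stack, "bf").sd
        assert sd[3, 3] == pytest.approx(1.0)

    def test_frame_order_permutation_invariant(self, small_synth):
        _, stack, _ = small_synth
        sd = im.temporal_sd_map(stack, "bf").sd
        rng = np.random.default_rng(0)
        perm = rng.permutation(stack.n_frames)
        shuffled = TimeLapseStack(channels={"bf": stack.channel("bf")[perm]},
                                  pixel_size=1.0, frame_interval=1.0)
        assert np.allclose(im.temporal_sd_map(shuffled, "bf").sd, sd)

    def test_peripheral_jitter_dominates_core(self):
        from spheroflow.synth import SyntheticConfig, render_timelapse

        cfg = SyntheticConfig(motile=True, noise_gaussian=0.0, poisson_scale=0.0,
                              seed=5, n_frames=20)
        stack, truth = render_timelapse(cfg)
        sd = im.temporal_sd_map(stack, "bf").sd
        roi = ROIMask(mask=truth.roi_mask)
        yy, xx = np.mgrid[0 : sd.shape[0], 0 : sd.shape[1]]
        rad = np.hypot(xx - roi.centroid[0], yy - roi.centroid[1])
        annulus = (rad > 0.9 * roi.equivalent_radius) & (rad < 1.3 * roi.equivalent_radius)
        core = rad < 0.5 * roi.equivalent_radius
        assert sd[annulus].mean() > 3 * sd[core].mean()

    def test_single_frame_rejected(self):
        stack = TimeLapseStack(channels={"bf": np.zeros((1, 8, 8))},
                               pixel_size=1.0, frame_interval=1.0)
        with pytest.raises(ValueError):
            im.temporal_sd_map(stack, "bf")


class TestPeripheralScore:
    def test_zero_map_scores_zero_with_warning(self):
        roi = ROIMask(mask=disk_mask((100, 100), (50, 50), 15))
        mot = im.MotilityMap(sd=np.zeros((100, 100)))
        with pytest.warns(UserWarning):
            assert im.peripheral_motility_score(mot, roi, 10.0) == 0.0

    def test_uniform_noise_movie_scores_near_one(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(0, 1, (30, 100, 100))
        stack = TimeLapseStack(channels={"bf": frames}, pixel_size=1.0,
                               frame_interval=1.0)
        roi = ROIMask(mask=disk_mask((100, 100), (50, 50), 15))
        score = im.peripheral_motility_score(im.temporal_sd_map(stack, "bf"), roi, 10.0)
        assert score == pytest.approx(1.0, abs=0.05)

    def test_motile_exceeds_static_in_paired_seeded_runs(self):
        from spheroflow.synth import SyntheticConfig, render_timelapse

        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            base = dict(image_size=(96, 96), pixel_size=3.0, spheroid_radius=60.0,
                        n_frames=10, seed=seed)
            stm, truth = render_timelapse(SyntheticConfig(motile=True, **base))
            sts, _ = render_timelapse(SyntheticConfig(motile=False, **base))
            roi = ROIMask(mask=truth.roi_mask)
            sm = im.peripheral_motility_score(
                im.temporal_sd_map(stm, "bf"), roi, 20.0, stm.pixel_size)
            ss = im.peripheral_motility_score(
                im.temporal_sd_map(sts, "bf"), roi, 20.0, sts.pixel_size)
            wins += sm > ss
        assert wins >= 0.95 * n_runs

    def test_empty_background_rejected(self):
        roi = ROIMask(mask=disk_mask((60, 60), (30, 30), 20))
        mot = im.MotilityMap(sd=np.ones((60, 60)))
        with pytest.raises(ValueError):
            im.peripheral_motility_score(mot, roi, 40.0)
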