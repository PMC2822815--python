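"""Phase-contrast pipeline: velocity mapping, background correction,
temporal unwrapping, vessel tracking and flow quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioflow import (
    Contour,
    ImageStack,
    VelocityField,
    compute_flow,
    correct_background,
    detect_stationary,
    fit_background,
    flow_profile_frames,
    flow_recovery_study,
    phase_to_velocity,
    track_vessel,
    unwrap_temporal,
    velocity_to_phase,
)
from cardioflow.phantom_synth import circle_contour
from conftest import uniform_stack


def vfield(v, venc=200.0, dt=0.05):
    return VelocityField(v, venc, (1.0, 1.0), dt)


class TestPhaseVelocity:
    def test_midpoint_and_linear_map(self):
        stack = uniform_stack(0.5, (8, 8), frames=3, image_type="phase", venc_cm_s=200)
        assert np.allclose(phase_to_velocity(stack).velocity_cm_s, 0.0)
        stack.voxels[:] = 0.75
        assert np.allclose(phase_to_velocity(stack).velocity_cm_s, 100.0)

    def test_round_trip_identity(self, rng):
        venc = 150.0
        v = rng.uniform(-venc, venc, (8, 8, 5))
        p = velocity_to_phase(v, venc)
        stack = ImageStack(p[:, :, None, :], pixel_spacing_mm=(1, 1),
                          slice_thickness_mm=8, time_increment_s=0.05,
                          image_type="phase", venc_cm_s=venc)
        back = phase_to_velocity(stack).velocity_cm_s
        assert np.max(np.abs(back - v)) < 1e-6 * venc

    def test_magnitude_stack_rejected(self):
        with pytest.raises(ValueError):
            phase_to_velocity(uniform_stack(0.5, (8, 8)))

    def test_nonpositive_venc_rejected(self):
        stack = uniform_stack(0.5, (8, 8), frames=3, image_type="phase", venc_cm_s=200)
        with pytest.raises(ValueError):
            phase_to_velocity(stack, venc_cm_s=-5)


class TestDetectStationary:
    def test_static_background_included_moving_excluded(self):
        v = np.zeros((10, 10, 8))
        t = np.arange(8)
        thr = 4.0
        v[5, 5, :] = 10 * thr * np.sin(2 * np.pi * t / 8)  # sd = A/sqrt(2) >> thr
        mask = detect_stationary(vfield(v), sd_threshold_cm_s=thr)
        assert mask[0, 0] and not mask[5, 5]

    def test_air_excluded_by_magnitude_floor(self):
        v = np.zeros((10, 10, 8))
        mag = uniform_stack(0.5, (10, 10), frames=8)
        mag.voxels[0:2, :, 0, :] = 0.02  # air: static phase but no signal
        mask = detect_stationary(vfield(v), sd_threshold_cm_s=1.0, magnitude=mag)
        assert not mask[0, 0] and mask[5, 5]

    def test_empty_mask_advises(self):
        v = np.random.default_rng(0).uniform(-50, 50, (6, 6, 8))
        with pytest.raises(ValueError, match="sd_threshold"):
            detect_stationary(vfield(v), sd_threshold_cm_s=1e-6)


def plane_field(a, b, v0, shape=(24, 24), frames=5):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    xc = xx - (shape[1] - 1) / 2
    yc = yy - (shape[0] - 1) / 2
    plane = v0 + a * xc + b * yc
    return vfield(np.repeat(plane[:, :, None], frames, axis=2)), plane


class TestBackgroundFit:
    def test_injected_plane_recovered_exactly(self):
        v, _ = plane_field(0.05, -0.02, 1.5)
        surf = fit_background(v, np.ones((24, 24), bool), order=1)
        coef = dict(zip(surf.exponents, surf.coefficients))
        assert coef[(1, 0)] == pytest.approx(0.05, abs=1e-9)
        assert coef[(0, 1)] == pytest.approx(-0.02, abs=1e-9)
        assert coef[(0, 0)] == pytest.approx(1.5, abs=1e-9)
        assert surf.residual_rms_cm_s < 1e-9

    def test_zero_field_zero_coefficients(self):
        v = vfield(np.zeros((24, 24, 4)))
        surf = fit_background(v, np.ones((24, 24), bool), order=2)
        assert np.max(np.abs(surf.coefficients)) < 1e-12

    def test_order1_fit_of_paraboloid_matches_ls_oracle(self):
        yy, xx = np.mgrid[0:20, 0:20].astype(float)
        xc, yc = xx - 9.5, yy - 9.5
        parab = 0.01 * xc**2 + 0.004 * yc**2
        v = vfield(np.repeat(parab[:, :, None], 4, axis=2))
        mask = np.ones((20, 20), bool)
        surf = fit_background(v, mask, order=1)
        # independent oracle: solve the normal equations explicitly
        design = np.stack([np.ones(400), yc.ravel(), xc.ravel()], axis=1)
        beta = np.linalg.solve(design.T @ design, design.T @ parab.ravel())
        resid = design @ beta - parab.ravel()
        assert surf.residual_rms_cm_s == pytest.approx(
            float(np.sqrt(np.mean(resid**2))), rel=1e-9)

    def test_collinear_mask_rejected(self):
        v = vfield(np.zeros((16, 16, 4)))
        mask = np.zeros((16, 16), bool)
        mask[7, 2:14] = True  # single row: y is constant
        with pytest.raises(ValueError, match="rank"):
            fit_background(v, mask, order=1)

    def test_too_small_mask_rejected(self):
        v = vfield(np.zeros((16, 16, 4)))
        mask = np.zeros((16, 16), bool)
        mask[4, 4:8] = True
        with pytest.raises(ValueError, match="mask pixels"):
            fit_background(v, mask, order=1)


class TestBackgroundCorrection:
    def test_correction_restores_truth(self, rng):
        truth = rng.uniform(-40, 40, (24, 24, 5))
        v, plane = plane_field(0.05, -0.02, 1.5)
        corrupted = vfield(truth + plane[:, :, None])
        still = np.abs(truth).max(axis=2) < 1e9  # fit over everything
        surf = fit_background(vfield(np.repeat(plane[:, :, None], 5, axis=2)),
                              still, order=1)
        restored = correct_background(corrupted, surf)
        assert np.max(np.abs(restored.velocity_cm_s - truth)) < 1e-9

    def test_roi_mean_shifts_by_surface_mean(self):
        v, plane = plane_field(0.05, -0.02, 1.5)
        surf = fit_background(v, np.ones((24, 24), bool), order=1)
        corrected = correct_background(v, surf)
        c = circle_contour(11, 11, 5.0)
        before = compute_flow(v, c).flow_ml_s[0]
        after = compute_flow(corrected, c).flow_ml_s[0]
        from cardioflow import rasterize
        mask = rasterize(c, (24, 24))
        shift = surf.evaluate()[mask].sum() * 0.01  # cm/s * cm^2 per pixel
        assert before - after == pytest.approx(shift, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        v, _ = plane_field(0.01, 0.0, 0.0, shape=(24, 24))
        surf = fit_background(v, np.ones((24, 24), bool), order=1)
        other = vfield(np.zeros((16, 16, 4)))
        with pytest.raises(ValueError):
            correct_background(other, surf)


class TestUnwrap:
    def test_wrap_pair_restored_exactly(self):
        venc = 200.0
        true = np.array([50.0, 150.0, 220.0, 150.0, 50.0])
        stored = (2 * velocity_to_phase(true, venc, wrap=True) - 1) * venc
        assert stored[2] == pytest.approx(-180.0)
        v = vfield(np.broadcast_to(stored, (2, 2, 5)).copy(), venc=venc)
        out = unwrap_temporal(v)
        assert np.allclose(out.velocity_cm_s[0, 0], true)
        assert not out.unwrap_flagged.any()

    def test_no_jump_identity(self, rng):
        v = rng.uniform(-90, 90, (6, 6, 8))
        out = unwrap_temporal(vfield(v))
        assert np.array_equal(out.velocity_cm_s, v)

    def test_unpaired_final_jump_flagged_unchanged(self):
        venc = 200.0
        series = np.array([0.0, 10.0, 20.0, 30.0, -350.0])
        v = vfield(np.broadcast_to(series, (1, 1, 5)).copy(), venc=venc)
        out = unwrap_temporal(v)
        assert np.array_equal(out.velocity_cm_s[0, 0], series)
        assert out.unwrap_flagged[0, 0]

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        v = vfield(rng.uniform(-200, 200, (5, 5, 8)))
        once = unwrap_temporal(v)
        twice = unwrap_temporal(once)
        assert np.array_equal(once.velocity_cm_s, twice.velocity_cm_s)


def disk_stack(frames, center=(20.0, 20.0), radius=13.0, drift=0.0, fade_at=None):
    vox = np.zeros((40, 40, 1, frames))
    yy, xx = np.mgrid[0:40, 0:40].astype(float)
    for f in range(frames):
        cx = center[0] + drift * f
        contrast = 0.8
        if fade_at is not None:
            contrast = 0.8 * max(0.0, 1.0 - f / fade_at)
        inside = (xx - cx) ** 2 + (yy - center[1]) ** 2 <= radius**2
        vox[:, :, 0, f] = 0.1 + contrast * inside
    return ImageStack(vox, pixel_spacing_mm=(1, 1), slice_thickness_mm=8,
                      time_increment_s=0.05)


class TestTrackVessel:
    def test_static_disk_tracked_within_2_percent(self):
        stack = disk_stack(20)
        c0 = circle_contour(20, 20, 13.0)
        contours, failed, reason = track_vessel(stack, c0)
        assert not failed, reason
        from cardioflow import polygon_area
        a0 = polygon_area(c0, (1, 1))
        areas = [polygon_area(c, (1, 1)) for c in contours]
        assert max(abs(a - a0) for a in areas) < 0.02 * a0

    def test_translating_disk_centroid_followed(self):
        drift = 0.5
        stack = disk_stack(12, drift=drift)
        contours, failed, _ = track_vessel(stack, circle_contour(20, 20, 13.0))
        assert not failed
        for f, c in enumerate(contours):
            cx = c.polygon.centroid.x
            assert abs(cx - (20 + drift * f)) < 0.5

    def test_contrast_collapse_raises_failure_flag(self):
        stack = disk_stack(15, fade_at=10)
        contours, failed, reason = track_vessel(stack, circle_contour(20, 20, 13.0))
        assert failed
        assert len(contours) == stack.frames
        frame = int(reason.rsplit("frame", 1)[1])
        assert frame <= 10

    def test_contour_outside_image_rejected(self):
        stack = disk_stack(5)
        with pytest.raises(ValueError):
            track_vessel(stack, circle_contour(60, 60, 5.0))


class TestComputeFlow:
    def test_uniform_velocity_arithmetic(self):
        v = vfield(np.full((20, 20, 10), 100.0))
        c = Contour(np.array([(2.5, 2.5), (12.5, 2.5), (12.5, 12.5), (2.5, 12.5)]))
        res = compute_flow(v, c)  # exactly 100 pixels of 1 mm^2
        assert np.allclose(res.flow_ml_s, 100.0)
        assert res.net_volume_ml == pytest.approx(50.0)
        assert res.area_mm2[0] == pytest.approx(100.0)

    def test_poiseuille_flow_within_3_percent(self):
        vmax, R = 80.0, 13.0
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        d2 = (xx - 20) ** 2 + (yy - 20) ** 2
        prof = np.where(d2 <= R**2, vmax * (1 - d2 / R**2), 0.0)
        v = vfield(np.repeat(prof[:, :, None], 4, axis=2))
        res = compute_flow(v, circle_contour(20, 20, R))
        assert res.flow_ml_s[0] == pytest.approx(
            vmax * np.pi * (R / 10) ** 2 / 2, rel=0.03)

    def test_reversed_flow_symmetry(self):
        frames = 10
        v = np.zeros((20, 20, frames))
        v[:, :, :5] = 60.0
        v[:, :, 5:] = -60.0
        res = compute_flow(vfield(v), circle_contour(10, 10, 6.0))
        assert res.net_volume_ml == pytest.approx(0.0, abs=1e-12)
        assert res.positive_volume_ml == pytest.approx(-res.negative_volume_ml)
        assert res.net_volume_ml == res.positive_volume_ml + res.negative_volume_ml

    def test_empty_mask_names_frame(self):
        v = vfield(np.zeros((20, 20, 3)))
        tiny = circle_contour(10.25, 10.25, 0.2)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="frame 0"):
                compute_flow(v, tiny)


class TestRecoveryStats:
    def test_identity_regression(self):
        r = flow_recovery_study([20, 40, 60, 80, 100], [20, 40, 60, 80, 100])
        assert r.slope == pytest.approx(1.0)
        assert r.intercept_ml == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_measured_zero_slope(self):
        r = flow_recovery_study([20, 40, 60], [50, 50, 50])
        assert r.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            flow_recovery_study([1, 2], [1, 2])


class TestFlowProfiles:
    def test_poiseuille_peak_at_center(self):
        vmax, R = 80.0, 10.0
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        d2 = (xx - 16) ** 2 + (yy - 16) ** 2
        prof = np.where(d2 <= R**2, vmax * (1 - d2 / R**2), 0.0)
        v = vfield(np.repeat(prof[:, :, None], 3, axis=2))
        frames = flow_profile_frames(v, circle_contour(16, 16, R))
        assert len(frames) == 3
        for surf in frames:
            r, c = np.unravel_index(np.ma.argmax(surf), surf.shape)
            assert (r, c) == (16, 16)

    def test_uniform_flow_flat_surfaces(self):
        v = vfield(np.full((20, 20, 2), 42.0))
        frames = flow_profile_frames(v, circle_contour(10, 10, 6.0))
        assert all(float(s.max() - s.min()) == 0.0 for s in frames)

    def test_zero_frames_empty_list(self):
        v = VelocityField(np.zeros((4, 4, 0)), 200.0)
        assert flow_profile_frames(v, {}) == []
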