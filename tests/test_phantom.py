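"""Synthetic subject generation: anatomy, FSF dynamics, echoes, motion,
cooling protocol."""

import dataclasses

import numpy as np
import pytest

from batlipid import (
    MotionParams,
    PhantomConfig,
    apply_motion,
    make_phantom,
    simulate_cooling_protocol,
    simulate_cooling_response,
    synthesize_echoes,
)
from batlipid.decades import decade_of
from batlipid.phantom import LABEL_BAT, LABEL_MUSCLE, LABEL_SAT, phantom_seed_masks
from batlipid.registration import slice_range_mask
from batlipid.segmentation import erode_once


@pytest.fixture(scope="module")
def default_phantom():
    return make_phantom(PhantomConfig(), seed=1)


class TestMakePhantom:
    def test_bat_mean_anchored(self, default_phantom):
        """BAT voxel FSF sample mean within 1 s.e. of the cohort mean."""
        labels, truth = default_phantom
        vals = truth.baseline_fsf[labels.mask(LABEL_BAT)]
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - 52.7) <= se

    def test_sat_mean_near_printed_value(self, default_phantom):
        labels, truth = default_phantom
        vals = truth.baseline_fsf[labels.mask(LABEL_SAT)]
        assert abs(vals.mean() - 89.3) < 1.0

    def test_default_grid_and_slices(self, default_phantom):
        labels, _ = default_phantom
        assert labels.labels.shape == (64, 64, 15)
        assert labels.n_slices == 15

    def test_all_decades_populated_in_analysis_roi(self, default_phantom):
        """>= 60 BAT voxels per decade within slices 6-13 after erosion."""
        labels, truth = default_phantom
        m = labels.mask(LABEL_BAT) & slice_range_mask(labels.labels.shape)
        m = erode_once(m)
        counts = np.bincount(decade_of(truth.baseline_fsf[m]), minlength=10)
        assert counts.min() >= 60

    def test_zero_sd_degenerates_to_mean(self):
        cfg = dataclasses.replace(PhantomConfig(), bat_voxel_sd=0.0)
        labels, truth = make_phantom(cfg, seed=1)
        vals = truth.baseline_fsf[labels.mask(LABEL_BAT)]
        assert np.all(vals == 52.7)

    def test_deterministic_for_fixed_seed(self):
        l1, t1 = make_phantom(PhantomConfig(), seed=9)
        l2, t2 = make_phantom(PhantomConfig(), seed=9)
        np.testing.assert_array_equal(l1.labels, l2.labels)
        np.testing.assert_array_equal(t1.baseline_fsf, t2.baseline_fsf)
        np.testing.assert_array_equal(t1.field_map_hz, t2.field_map_hz)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(shape=(2, 2))
        with pytest.raises(ValueError):
            PhantomConfig(bat_voxel_sd=-1.0)

    def test_baseline_in_range_and_slopes_by_decade(self, default_phantom):
        labels, truth = default_phantom
        body = labels.labels > 0
        assert truth.baseline_fsf[body].min() >= 0
        assert truth.baseline_fsf[body].max() <= 100
        cfg = PhantomConfig()
        bat = labels.mask(LABEL_BAT)
        dec = decade_of(truth.baseline_fsf[bat])
        expected = np.asarray(cfg.bat_decade_changes)[dec] / cfg.full_protocol_dose
        np.testing.assert_allclose(truth.slopes[bat], expected)


class TestCoolingResponse:
    def test_zero_dose_equals_baseline(self, default_phantom):
        _, truth = default_phantom
        out = simulate_cooling_response(truth, [0.0, 0.0, 0.0], noise_sd=0.0)
        for t in range(3):
            np.testing.assert_array_equal(out[t], np.clip(truth.baseline_fsf, 0, 100))

    def test_anchored_decade_changes_at_full_dose(self, default_phantom):
        """Noise-free endpoint change matches the configured anchors: the
        90s decade loses ~14.4 pp, the 0s decade gains ~6.7 pp."""
        labels, truth = default_phantom
        cfg = PhantomConfig()
        D = cfg.full_protocol_dose
        out = simulate_cooling_response(truth, [0.0, D], noise_sd=0.0)
        bat = labels.mask(LABEL_BAT)
        dec = decade_of(truth.baseline_fsf)
        d9 = bat & (dec == 9)
        d0 = bat & (dec == 0)
        ch9 = (out[1] - out[0])[d9].mean()
        ch0 = (out[1] - out[0])[d0].mean()
        assert ch9 == pytest.approx(-14.4, abs=0.3)  # slight clipping at 100
        assert ch0 == pytest.approx(6.7, abs=0.1)

    def test_decade_conditional_monotonicity(self, default_phantom):
        """Noise-free decade means: nonincreasing in dose for decades >= 60,
        nondecreasing for decades <= 20."""
        labels, truth = default_phantom
        doses = np.linspace(0, 360, 5)
        out = simulate_cooling_response(truth, doses, noise_sd=0.0)
        bat = labels.mask(LABEL_BAT)
        dec = decade_of(truth.baseline_fsf)
        for d in range(10):
            m = bat & (dec == d)
            means = out[:, m].mean(axis=1)
            if d >= 6:
                assert np.all(np.diff(means) <= 1e-9)
            if d <= 2:
                assert np.all(np.diff(means) >= -1e-9)

    def test_series_stays_in_range(self, default_phantom):
        _, truth = default_phantom
        out = simulate_cooling_response(truth, [0, 500, 2000], noise_sd=3.0, seed=0)
        assert out.min() >= 0 and out.max() <= 100

    def test_decreasing_dose_rejected(self, default_phantom):
        _, truth = default_phantom
        with pytest.raises(ValueError, match="nondecreasing"):
            simulate_cooling_response(truth, [0.0, 100.0, 50.0])
        with pytest.raises(ValueError, match="start at 0"):
            simulate_cooling_response(truth, [10.0, 100.0])


class TestApplyMotion:
    def _series(self, schedule, spectrum, shape=(16, 16, 5)):
        rng = np.random.default_rng(0)
        fsf = rng.uniform(0, 100, shape)
        return synthesize_echoes(fsf, spectrum, np.zeros(shape), np.zeros(shape),
                                 schedule)

    def test_zero_amplitude_identity(self, schedule, spectrum):
        ser = self._series(schedule, spectrum)
        out, field = apply_motion(ser, MotionParams(amplitude_vox=0.0), seed=0)
        np.testing.assert_array_equal(out.data, ser.data)
        assert not field.disp.any()

    def test_translation_three_four_five(self, schedule, spectrum):
        """In-plane (3, 4) translation displaces every point by 5 voxels."""
        ser = self._series(schedule, spectrum, shape=(24, 24, 3))
        out, field = apply_motion(ser, MotionParams(translation=(3.0, 4.0, 0.0)))
        disp = np.linalg.norm(field.disp[..., :2], axis=-1)
        np.testing.assert_allclose(disp, 5.0)
        # content moved by exactly (3, 4): interior voxels equal the shifted
        # original
        np.testing.assert_allclose(
            out.data[5:20, 6:20, :, 0], ser.data[2:17, 2:16, :, 0], atol=1e-9
        )

    def test_smooth_field_reproducible(self, schedule, spectrum):
        ser = self._series(schedule, spectrum)
        out1, f1 = apply_motion(ser, MotionParams(amplitude_vox=1.5), seed=5)
        out2, f2 = apply_motion(ser, MotionParams(amplitude_vox=1.5), seed=5)
        np.testing.assert_array_equal(out1.data, out2.data)
        np.testing.assert_array_equal(f1.disp, f2.disp)

    def test_median_inplane_amplitude_calibrated(self, schedule, spectrum):
        ser = self._series(schedule, spectrum)
        out, field = apply_motion(ser, MotionParams(amplitude_vox=1.2), seed=5)
        med = np.median(np.linalg.norm(field.disp[..., :2], axis=-1))
        assert med == pytest.approx(1.2, rel=1e-6)

    def test_excessive_amplitude_rejected(self, schedule, spectrum):
        ser = self._series(schedule, spectrum)
        with pytest.raises(ValueError, match="grid"):
            apply_motion(ser, MotionParams(amplitude_vox=100.0), seed=0)
        with pytest.raises(ValueError, match="grid"):
            apply_motion(ser, MotionParams(translation=(50.0, 0, 0)))

    def test_inverse_consistency(self, schedule, spectrum):
        """Warping the corrupted series by the returned correction field
        approximately restores the original (smooth content, so the check
        probes the field inversion rather than interpolation error)."""
        from scipy.ndimage import gaussian_filter

        from batlipid.registration import warp_scalar

        rng = np.random.default_rng(0)
        shape = (32, 32, 5)
        fsf = gaussian_filter(rng.uniform(0, 100, shape), (3, 3, 1))
        fsf = 100 * (fsf - fsf.min()) / (fsf.max() - fsf.min())
        ser = synthesize_echoes(fsf, spectrum, np.zeros(shape), np.zeros(shape),
                                schedule)
        out, field = apply_motion(ser, MotionParams(amplitude_vox=2.0), seed=3)
        rec = warp_scalar(np.abs(out.data[..., 0]), field)
        orig = np.abs(ser.data[..., 0])
        interior = np.s_[4:-4, 4:-4, 1:-1]
        rms = np.sqrt(((rec - orig)[interior] ** 2).mean())
        assert rms < 0.05 * orig.max()


class TestCoolingProtocol:
    def test_final_set_temperature(self):
        """ST = 15.6, thermoneutral 32: protocol ends at ST + 3 = 18.6."""
        profile, _ = simulate_cooling_protocol(15.6, 32.0, 60.0, seed=0)
        assert profile.set_temp_c[-1] == pytest.approx(18.6)

    def test_thirty_second_cadence(self):
        profile, sensation = simulate_cooling_protocol(15.6, 32.0, 30.0, seed=0)
        np.testing.assert_allclose(np.diff(profile.time_min), 0.5)
        np.testing.assert_allclose(np.diff(sensation.time_min), 0.5)

    def test_zero_duration_single_thermoneutral_sample(self):
        profile, _ = simulate_cooling_protocol(15.6, 32.0, 0.0, seed=0)
        assert profile.time_min.size == 1
        assert profile.set_temp_c[0] == 32.0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_cooling_protocol(15.6, 32.0, -1.0)

    def test_thermoneutral_must_exceed_st_plus_six(self):
        with pytest.raises(ValueError, match="shiver"):
            simulate_cooling_protocol(28.0, 32.0, 30.0)

    def test_sensation_monotone_from_neutral(self):
        _, sensation = simulate_cooling_protocol(15.6, 32.0, 60.0, seed=4)
        assert sensation.sensation[0] == 50
        assert np.all(np.diff(sensation.sensation) <= 0)
        assert sensation.sensation.min() >= 0

    def test_deterministic_for_fixed_seed(self):
        _, s1 = simulate_cooling_protocol(15.6, 32.0, 45.0, seed=8)
        _, s2 = simulate_cooling_protocol(15.6, 32.0, 45.0, seed=8)
        np.testing.assert_array_equal(s1.sensation, s2.sensation)


class TestFiducials:
    def test_nine_points_on_four_slices_at_boundaries(self, default_phantom):
        from batlipid.phantom import phantom_fiducials

        labels, _ = default_phantom
        fids = phantom_fiducials(labels)
        assert len(fids.labels) == 9
        assert len(set(p[0] for p in fids.points)) == 4  # four slices
        for s, r, c in fids.points:
            assert 0 <= r < labels.labels.shape[0]
            assert 0 <= c < labels.labels.shape[1]


class TestSeedMasks:
    def test_partition_of_bat(self, default_phantom):
        labels, _ = default_phantom
        seeds = phantom_seed_masks(labels)
        bat = labels.mask(LABEL_BAT)
        np.testing.assert_array_equal(seeds["bat_left"] | seeds["bat_right"], bat)
        assert not (seeds["bat_left"] & seeds["bat_right"]).any()
        np.testing.assert_array_equal(seeds["muscle"], labels.mask(LABEL_MUSCLE))
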