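"""Echo scheduling, the forward signal model and fat-water separation."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from batlipid import (
    EchoSchedule,
    FatSpectrum,
    FSFVolume,
    SeparationOptions,
    build_echo_schedule,
    compute_fsf_map,
    drop_leading_train_echoes,
    separate_fat_water,
    synthesize_echoes,
)
from batlipid.fatwater import EchoSeries


def forward_model_oracle(fsf, psi, r2, te_s, spectrum, amplitude=100.0):
    """Literal transcription of the closed-form signal model (independent
    of the vectorized implementation in the package)."""
    F = amplitude * fsf / 100.0
    W = amplitude - F
    out = np.empty(len(te_s), dtype=complex)
    for k, te in enumerate(te_s):
        c = 0.0 + 0.0j
        for a, df in zip(spectrum.rel_amplitudes, spectrum.freq_offsets_hz):
            c += a * np.exp(1j * 2 * np.pi * df * te)
        out[k] = (W + F * c) * np.exp(1j * 2 * np.pi * psi * te) * np.exp(-r2 * te)
    return out


class TestEchoSchedule:
    def test_default_table_values(self, schedule):
        assert schedule.n_echoes == 18
        assert round(schedule.te_ms[3], 2) == 3.61  # 4th echo
        assert round(schedule.te_ms[-1], 2) == 13.92

    def test_uniform_simple_schedule(self):
        s = build_echo_schedule(6, 1.0, 1.0, 1)
        assert np.allclose(s.te_ms, [1, 2, 3, 4, 5, 6])

    def test_non_divisible_counts_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_echo_schedule(10, 1.0, 1.0, 3)

    def test_trains_partition_echoes(self, schedule):
        assert sorted(schedule.train_index) == sorted([0, 1, 2] * 6)
        assert schedule.train_lengths().tolist() == [6, 6, 6]


class TestDropLeadingTrainEchoes:
    def test_default_drops_three(self, schedule, spectrum):
        data = np.ones((2, 2, 1, 18), dtype=complex)
        out = drop_leading_train_echoes(EchoSeries(data, schedule))
        assert out.data.shape[-1] == 15
        assert round(out.schedule.te_ms[0], 2) == 3.61

    def test_single_train(self):
        s = build_echo_schedule(6, 1.0, 1.0, 1)
        out = drop_leading_train_echoes(EchoSeries(np.ones((1, 1, 1, 6), complex), s))
        assert out.data.shape[-1] == 5

    def test_not_idempotent(self, schedule):
        ser = EchoSeries(np.ones((1, 1, 1, 18), complex), schedule)
        once = drop_leading_train_echoes(ser)
        twice = drop_leading_train_echoes(once)
        assert twice.data.shape[-1] == 12  # drops another echo per train

    def test_length_one_train_rejected(self):
        s = build_echo_schedule(3, 1.0, 1.0, 3)
        with pytest.raises(ValueError, match="at least 2"):
            drop_leading_train_echoes(EchoSeries(np.ones((1, 1, 1, 3), complex), s))


class TestFatSpectrum:
    def test_default_normalized_seven_peaks(self, spectrum):
        assert spectrum.n_peaks == 7
        assert abs(sum(spectrum.rel_amplitudes) - 1.0) < 1e-12

    def test_unnormalized_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FatSpectrum((0.5, 0.4), (-434.0, -300.0))


class TestForwardModel:
    def test_matches_independent_oracle(self, schedule, spectrum, rng):
        """Vectorized synthesis equals a literal transcription at 1e-12."""
        n = 1000
        fsf = rng.uniform(0, 100, n)
        psi = rng.uniform(-150, 150, n)
        r2 = rng.uniform(0, 120, n)
        series = synthesize_echoes(
            fsf.reshape(-1, 1, 1), spectrum, psi.reshape(-1, 1, 1),
            r2.reshape(-1, 1, 1), schedule,
        )
        te = schedule.te_s
        for i in range(0, n, 37):
            expected = forward_model_oracle(fsf[i], psi[i], r2[i], te, spectrum)
            np.testing.assert_allclose(
                series.data[i, 0, 0], expected, rtol=0, atol=1e-9
            )
        # full check vectorized against the scalar oracle on a subsample
        sample = rng.integers(0, n, 100)
        for i in sample:
            expected = forward_model_oracle(fsf[i], psi[i], r2[i], te, spectrum)
            assert np.max(np.abs(series.data[i, 0, 0] - expected)) < 1e-9 * 100

    def test_pure_water_constant_magnitude(self, schedule, spectrum):
        ser = synthesize_echoes(
            np.zeros((1, 1, 1)), spectrum, np.zeros((1, 1, 1)),
            np.zeros((1, 1, 1)), schedule,
        )
        mags = np.abs(ser.data[0, 0, 0])
        np.testing.assert_allclose(mags, mags[0])

    def test_pure_fat_single_peak_phase_advance(self, schedule):
        """FSF=100 with one fat peak: constant magnitude, linear phase."""
        df = -434.0
        single = FatSpectrum.single_peak(df)
        psi = 10.0
        ser = synthesize_echoes(
            np.full((1, 1, 1), 100.0), single, np.full((1, 1, 1), psi),
            np.zeros((1, 1, 1)), schedule,
        )
        sig = ser.data[0, 0, 0]
        np.testing.assert_allclose(np.abs(sig), np.abs(sig[0]))
        expected_phase = 2 * np.pi * (df + psi) * schedule.te_s
        ratio = sig / (100.0 * np.exp(1j * expected_phase))
        np.testing.assert_allclose(ratio, 1.0, atol=1e-12)

    def test_fsf_out_of_range_rejected(self, schedule, spectrum):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            synthesize_echoes(
                np.full((1, 1, 1), 101.0), spectrum, np.zeros((1, 1, 1)),
                np.zeros((1, 1, 1)), schedule,
            )


def _single_voxel_series(fsf, psi, r2, schedule, spectrum):
    ser = synthesize_echoes(
        np.full((1, 1, 1), float(fsf)), spectrum,
        np.full((1, 1, 1), float(psi)), np.full((1, 1, 1), float(r2)), schedule,
    )
    return drop_leading_train_echoes(ser)


class TestSeparation:
    def test_pure_water_noiseless(self, schedule, spectrum):
        ser = _single_voxel_series(0.0, 0.0, 0.0, schedule, spectrum)
        res = separate_fat_water(ser, spectrum)
        f_frac = res.fat / (res.fat + res.water)
        assert abs(f_frac[0, 0, 0]) < 1e-9

    def test_noiseless_recovery_fsf40(self, schedule, spectrum):
        ser = _single_voxel_series(40.0, 30.0, 40.0, schedule, spectrum)
        res = separate_fat_water(ser, spectrum)
        fsf = compute_fsf_map(res, 0.0)
        assert abs(fsf.fsf[0, 0, 0] - 40.0) < 0.01
        assert abs(res.field_map_hz[0, 0, 0] - 30.0) < 0.1

    @pytest.mark.parametrize("fsf_true", list(range(0, 101, 10)))
    def test_parameter_recovery_sweep(self, schedule, spectrum, fsf_true):
        """(W, F, psi, R2*) recovered to <= 0.1% relative error, noiselessly."""
        psi_t, r2_t = 25.0, 45.0
        ser = _single_voxel_series(fsf_true, psi_t, r2_t, schedule, spectrum)
        res = separate_fat_water(ser, spectrum)
        w_t, f_t = 100.0 - fsf_true, float(fsf_true)
        for est, true in (
            (res.water[0, 0, 0], w_t),
            (res.fat[0, 0, 0], f_t),
            (res.field_map_hz[0, 0, 0], psi_t),
            (res.r2star[0, 0, 0], r2_t),
        ):
            if true == 0:
                assert abs(est) < 1e-3
            else:
                assert abs(est - true) / abs(true) < 1e-3

    def test_smooth_field_slab_no_swaps(self, schedule, spectrum):
        """<= 0.1% of voxels swapped on a noiseless slab with a smooth
        field map."""
        rng = np.random.default_rng(5)
        shape = (24, 24, 4)
        fsf = rng.uniform(0, 100, shape)
        psi = gaussian_filter(rng.standard_normal(shape), (5, 5, 2))
        psi *= 80.0 / np.abs(psi).max()
        ser = drop_leading_train_echoes(
            synthesize_echoes(fsf, spectrum, psi, np.full(shape, 40.0), schedule)
        )
        res = separate_fat_water(ser, spectrum)
        m = compute_fsf_map(res, 0.0)
        swap_rate = np.mean(np.abs(m.fsf - fsf) > 50)
        assert swap_rate <= 0.001

    def test_min_echo_count_enforced(self, spectrum):
        s = build_echo_schedule(3, 1.0, 1.0, 1)
        with pytest.raises(ValueError, match="at least 4"):
            separate_fat_water(EchoSeries(np.ones((1, 1, 1, 3), complex), s), spectrum)

    def test_all_zero_voxel_flagged_invalid(self, schedule, spectrum):
        data = np.zeros((2, 1, 1, 15), dtype=complex)
        ser = _single_voxel_series(40.0, 0.0, 30.0, schedule, spectrum)
        data[0] = ser.data[0, 0, 0]
        s2 = EchoSeries(data, ser.schedule)
        res = separate_fat_water(s2, spectrum)
        assert res.valid[0, 0, 0]
        assert not res.valid[1, 0, 0]


class TestComputeFsfMap:
    def _result(self, water, fat):
        from batlipid.fatwater import SeparationResult

        shape = np.asarray(water, float).shape
        return SeparationResult(
            water=np.asarray(water, float),
            fat=np.asarray(fat, float),
            field_map_hz=np.zeros(shape),
            r2star=np.zeros(shape),
            residual=np.zeros(shape),
            valid=np.ones(shape, bool),
            first_echo_magnitude=np.asarray(water, float) + np.asarray(fat, float),
        )

    def test_pure_water_zero_percent(self):
        m = compute_fsf_map(self._result([[[100.0]]], [[[0.0]]]), 0.0)
        assert m.fsf[0, 0, 0] == 0.0

    def test_fat_dominant_branch(self):
        m = compute_fsf_map(self._result([[[40.0]]], [[[60.0]]]), 0.0)
        assert abs(m.fsf[0, 0, 0] - 60.0) < 1e-12

    def test_branch_identity_on_noiseless_inputs(self, rng):
        w = rng.uniform(0, 100, (5, 5, 2))
        f = rng.uniform(0, 100, (5, 5, 2))
        tot = w + f
        water_dom = 100 * f / tot
        fat_dom = 100 * (1 - w / tot)
        np.testing.assert_allclose(water_dom, fat_dom, atol=1e-12)
        m = compute_fsf_map(self._result(w, f), 0.0)
        np.testing.assert_allclose(m.fsf, water_dom, atol=1e-9)

    def test_zero_total_signal_invalid(self):
        m = compute_fsf_map(self._result([[[0.0]]], [[[0.0]]]), 0.0)
        assert not m.valid[0, 0, 0]

    def test_masking_partitions_grid(self, schedule, spectrum, rng):
        shape = (8, 8, 3)
        fsf = rng.uniform(0, 100, shape)
        amp = np.where(rng.uniform(size=shape) > 0.3, 100.0, 0.0)
        ser = drop_leading_train_echoes(
            synthesize_echoes(fsf, spectrum, np.zeros(shape), np.zeros(shape),
                              schedule, amplitude=amp)
        )
        res = separate_fat_water(ser, spectrum)
        m = compute_fsf_map(res)
        assert m.valid.sum() + (~m.valid).sum() == np.prod(shape)
        assert m.valid.sum() == (amp > 0).sum()

    def test_accuracy_on_noisy_slab(self, schedule, spectrum):
        """Mean |FSF - truth| < 1 pp at SNR 50."""
        rng = np.random.default_rng(11)
        shape = (24, 24, 3)
        fsf = rng.uniform(0, 100, shape)
        psi = gaussian_filter(rng.standard_normal(shape), (5, 5, 1))
        psi *= 40.0 / np.abs(psi).max()
        ser = drop_leading_train_echoes(
            synthesize_echoes(fsf, spectrum, psi, np.full(shape, 50.0), schedule,
                              noise_sd=2.0, seed=4)
        )
        res = separate_fat_water(ser, spectrum)
        m = compute_fsf_map(res, 0.0)
        assert np.nanmean(np.abs(m.fsf - fsf)) < 1.0


class TestFSFVolume:
    def test_out_of_range_flagged_not_zeroed(self):
        raw = np.array([[[-5.0, 50.0, 104.0]]])
        vol = FSFVolume.from_raw(raw, np.ones_like(raw, bool))
        assert not vol.valid[0, 0, 0] and not vol.valid[0, 0, 2]
        assert vol.valid[0, 0, 1]
        assert vol.fsf[0, 0, 0] == -5.0  # raw value kept

    def test_valid_range_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            FSFVolume(np.array([[[120.0]]]), np.array([[[True]]]))
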