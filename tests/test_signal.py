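"""Signal processing: ENMO, vector magnitude, windows, steady state, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from wristcut.signal import (CalibrationParams, TrialFeatures, autocalibrate,
                             apply_calibration, compute_enmo, extract_window,
                             steady_state_check, summarize_trial,
                             vector_magnitude)
from wristcut.synth import TrialRecording

from conftest import static_orientation_signal


def constant_raw(sample, n=90):
    return np.tile(np.asarray(sample, dtype=float), (n, 1))


class TestEnmo:
    @pytest.mark.parametrize("sample,expected_mg", [
        ((0.6, 0.8, 0.0), 0.0),     # unit norm: pure gravity
        ((1.2, 0.0, 0.0), 200.0),   # norm - 1 = 0.2 g
        ((0.5, 0.0, 0.0), 0.0),     # negative values clip to zero, not -500
    ])
    def test_constant_samples(self, sample, expected_mg):
        es = compute_enmo(constant_raw(sample))
        assert es.values == pytest.approx(expected_mg)
        assert es.epoch_length == 1.0

    def test_rotation_invariance(self, rng):
        raw = rng.normal(scale=0.4, size=(300, 3)) + np.array([0, 0, 1.0])
        base = compute_enmo(raw).values
        for rot in Rotation.random(5, rng=rng):
            rotated = raw @ rot.as_matrix().T
            np.testing.assert_allclose(compute_enmo(rotated).values, base,
                                       rtol=1e-10, atol=1e-10)

    def test_epoch_grid(self):
        es = compute_enmo(constant_raw((1.1, 0, 0), n=95))  # 3 full 1-s epochs
        np.testing.assert_array_equal(es.starts, [0.0, 1.0, 2.0])


class TestVectorMagnitude:
    def test_pythagorean_triple(self):
        assert vector_magnitude(3, 4, 0) == pytest.approx(5.0)
        assert vector_magnitude(0, 0, 0) == 0.0
        assert vector_magnitude(100, 100, 100) == pytest.approx(173.20508075688772)

    def test_single_axis_identity(self):
        assert vector_magnitude(7.5, 0, 0) == pytest.approx(7.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            vector_magnitude(-1, 0, 0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0, 1e4), st.floats(0, 1e4), st.floats(0, 1e4),
           st.floats(0, 100))
    def test_monotone_in_each_argument(self, va, ml, ap, bump):
        base = vector_magnitude(va, ml, ap)
        assert vector_magnitude(va + bump, ml, ap) >= base
        assert vector_magnitude(va, ml + bump, ap) >= base
        assert vector_magnitude(va, ml, ap + bump) >= base


class TestWindow:
    def test_standard_and_lying_windows(self):
        assert extract_window("RU", 300.0) == (150.0, 270.0)
        assert extract_window("LD", 600.0) == (420.0, 540.0)

    def test_windows_are_two_minutes(self):
        for code, dur in (("RU", 300.0), ("LD", 600.0)):
            lo, hi = extract_window(code, dur)
            assert hi - lo == 120.0

    def test_truncated_trial_rejected(self):
        with pytest.raises(ValueError):
            extract_window("RU", 200.0)


class TestSteadyState:
    def test_constant_series_pass(self):
        assert steady_state_check(np.full(8, 120.0), np.full(8, 900.0))

    def test_hr_beyond_five_bpm_fails(self):
        hr = np.array([114.0, 126.0] * 4)  # 6 bpm from the mean
        assert not steady_state_check(hr, np.full(8, 900.0))

    def test_vo2_within_ten_percent_passes(self):
        vo2 = np.array([900.0, 1020.0] * 4)  # 6.25% around mean 960
        assert steady_state_check(np.full(8, 130.0), vo2)

    def test_vo2_beyond_ten_percent_fails(self):
        vo2 = np.array([850.0, 1100.0] * 4)
        assert not steady_state_check(np.full(8, 130.0), vo2)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            steady_state_check(np.array([120.0]), np.array([900.0]))


class TestAutocalibration:
    def test_identity_fixed_point(self, rng):
        raw = static_orientation_signal(rng)
        cal = autocalibrate(raw)
        assert cal.converged
        np.testing.assert_allclose(cal.gain, 1.0, atol=2e-3)
        np.testing.assert_allclose(cal.offset, 0.0, atol=2e-3)

    def test_known_distortion_recovered(self, rng):
        raw = static_orientation_signal(rng)
        gain = np.array([1.05, 0.95, 1.02])
        offset = np.array([0.02, -0.03, 0.0])
        cal = autocalibrate(raw * gain + offset)
        assert cal.converged
        g_imp, o_imp = cal.implied_distortion
        np.testing.assert_allclose(g_imp, gain, atol=0.01)
        np.testing.assert_allclose(o_imp, offset, atol=0.01)

    def test_pure_dynamic_signal_returns_identity(self, rng):
        raw = rng.normal(scale=0.5, size=(30 * 120, 3))  # never still
        cal = autocalibrate(raw)
        assert not cal.converged
        assert cal.gain == (1.0, 1.0, 1.0)
        assert cal.offset == (0.0, 0.0, 0.0)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            autocalibrate(rng.standard_normal((30 * 30, 3)))

    def test_recalibrating_calibrated_data_barely_moves_enmo(self, rng):
        raw = static_orientation_signal(rng)
        cal = autocalibrate(raw)
        before = compute_enmo(raw).values
        after = compute_enmo(apply_calibration(raw, cal)).values
        assert abs(np.median(after) - np.median(before)) < 1.0  # < 1 milli-g


def make_counts_trial(va_epochs, duration=300.0):
    n = len(va_epochs)
    counts = np.column_stack([np.arange(n) * 5.0, va_epochs,
                              np.zeros(n), np.zeros(n)])
    gas_t = np.arange(15.0, duration + 1e-9, 15.0)
    return TrialRecording(
        participant_id="PX", activity_code="CW", raw_left=None, raw_right=None,
        counts_left=counts, counts_right=counts, gas_t=gas_t,
        vo2=np.full(gas_t.size, 1200.0), hr=np.full(gas_t.size, 120.0))


class TestSummarizeTrial:
    def test_constant_counts_mean(self):
        feats = summarize_trial(make_counts_trial(np.full(60, 250.0)))
        assert feats.mean_va["left"] == pytest.approx(250.0)
        assert feats.mean_vm["right"] == pytest.approx(250.0)  # single-axis VM
        assert feats.steady_state
        assert isinstance(feats, TrialFeatures)

    def test_alternating_counts_mean(self):
        va = np.tile([200.0, 300.0], 30)
        feats = summarize_trial(make_counts_trial(va))
        assert feats.mean_va["left"] == pytest.approx(250.0)  # 24 epochs in window

    def test_enmo_side_uses_calibration(self, participant, profiles, rng):
        from wristcut.synth import generate_trial

        trial = generate_trial(participant, profiles["LD"], seed=77)
        ident = summarize_trial(trial)
        shifted = summarize_trial(trial, {"right": CalibrationParams(
            gain=(1.0, 1.0, 1.0), offset=(0.05, 0.0, 0.0), converged=True)})
        assert shifted.mean_enmo["right"] != pytest.approx(ident.mean_enmo["right"])
        assert shifted.mean_enmo["left"] == pytest.approx(ident.mean_enmo["left"])
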