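"""Synthetic cohort generator: catalogue transcription, distributions, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from wristcut import generate_participants, generate_trial, summarize_trial
from wristcut.config import RunConfig
from wristcut.synth import (ACTIVITY_CODES, CalibrationError,
                            builtin_activity_profiles, generate_cohort,
                            lognormal_from_quartiles)


class TestActivityCatalogue:
    def test_twelve_unique_profiles(self, profiles):
        assert len(profiles) == 12
        assert set(profiles) == set(ACTIVITY_CODES)

    def test_run_profile_values(self, profiles):
        ru = profiles["RU"]
        assert ru.met_mean == 9.7
        assert ru.met_sd == 2.3
        assert ru.va_median == 1392
        assert ru.enmo_median == 558.7

    def test_lying_profile_zero_count_medians(self, profiles):
        ld = profiles["LD"]
        assert ld.va_median == 0
        assert ld.vm_median == 0

    def test_postures_and_durations(self, profiles):
        assert profiles["LD"].posture == "lying"
        assert profiles["HW"].posture == "sitting"
        assert profiles["CG"].posture == "sitting"
        upright = set(ACTIVITY_CODES) - {"LD", "HW", "CG"}
        assert all(profiles[c].posture == "upright" for c in upright)
        assert profiles["LD"].duration == 600.0
        assert all(profiles[c].duration == 300.0 for c in ACTIVITY_CODES if c != "LD")


class TestParticipants:
    def test_ages_within_bounds_and_deterministic(self):
        a = generate_participants(18, seed=1)
        b = generate_participants(18, seed=1)
        assert all(8.0 <= p.age <= 18.0 for p in a)
        assert a == b
        assert len({p.id for p in a}) == 18

    def test_sex_ratio_default(self):
        parts = generate_participants(18, seed=3)
        assert sum(p.sex == "male" for p in parts) == 10

    def test_age_distribution_mean(self):
        # oracle: mean of normal(14.6, 2.4) truncated to [8, 18]; the upper
        # truncation pulls it below 14.6, to ~14.24
        from scipy.stats import truncnorm

        a, b = (8 - 14.6) / 2.4, (18 - 14.6) / 2.4
        expected = truncnorm.mean(a, b, loc=14.6, scale=2.4)
        parts = generate_participants(1000, seed=2)
        ages = np.array([p.age for p in parts])
        assert abs(ages.mean() - expected) < 0.25

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            generate_participants(0, seed=1)


class TestMetricDistributionFit:
    def test_positive_quartiles_round_trip(self):
        fit = lognormal_from_quartiles(250, 220, 287)
        q = fit.ppf(np.array([0.25, 0.5, 0.75]))
        assert q[1] == pytest.approx(250)
        # the fit matches the IQR *width* around the reported median
        assert q[2] - q[0] == pytest.approx(287 - 220, rel=1e-9)

    def test_zero_median_mixture(self):
        fit = lognormal_from_quartiles(0, 0, 20)
        q = fit.ppf(np.array([0.25, 0.5, 0.75]))
        assert q[0] == 0 and q[1] == 0
        assert q[2] == pytest.approx(20)

    def test_zero_lower_quartile_mixture(self):
        fit = lognormal_from_quartiles(5, 0, 11)
        q = fit.ppf(np.array([0.25, 0.5, 0.75]))
        assert q[0] == 0
        assert q[1] == pytest.approx(5)
        assert q[2] == pytest.approx(11)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(median=st.floats(1.0, 2000.0), lo_f=st.floats(0.05, 0.99),
           width_f=st.floats(0.05, 2.0))
    def test_quartile_fit_property(self, median, lo_f, width_f):
        q25 = median * lo_f
        q75 = q25 + width_f * median
        fit = lognormal_from_quartiles(median, q25, q75)
        q = fit.ppf(np.array([0.25, 0.5, 0.75]))
        assert q[1] == pytest.approx(median, rel=1e-9)
        assert q[2] - q[0] == pytest.approx(q75 - q25, rel=1e-6)


class TestGenerateTrial:
    def test_deterministic_given_seed(self, participant, profiles):
        a = generate_trial(participant, profiles["CW"], seed=7)
        b = generate_trial(participant, profiles["CW"], seed=7)
        np.testing.assert_array_equal(a.raw_left, b.raw_left)
        np.testing.assert_array_equal(a.counts_right, b.counts_right)
        np.testing.assert_array_equal(a.vo2, b.vo2)

    def test_lying_trial_is_near_still(self, participant, profiles):
        vas, enmos = [], []
        for s in range(20):
            t = generate_trial(participant, profiles["LD"], seed=300 + s)
            f = summarize_trial(t)
            vas.append(f.mean_va["right"])
            enmos.append(f.mean_enmo["right"])
        assert np.median(vas) <= 20  # counts essentially zero while lying
        lo, hi = profiles["LD"].enmo_iqr
        assert lo <= np.median(enmos) <= hi

    def test_run_mets_tail_matches_normal_oracle(self, participant, profiles):
        # drawn METs >= 6 should occur with P(N(9.7, 2.3) >= 6) ~ 0.946
        cfg = RunConfig()
        from wristcut.energy import schofield_ree, youth_mets

        ree = schofield_ree(participant.sex, participant.age, participant.mass,
                            participant.height)
        hits = 0
        n = 60
        for s in range(n):
            t = generate_trial(participant, profiles["RU"], seed=900 + s, config=cfg)
            f = summarize_trial(t)
            hits += youth_mets(f.mean_vo2, participant.mass, ree) >= 6.0
        p_oracle = 1.0 - norm.cdf((6.0 - 9.7) / 2.3)
        se = math.sqrt(p_oracle * (1 - p_oracle) / n)
        assert abs(hits / n - p_oracle) < 4 * se + 0.02  # ramp shrinks METs ~1%

    def test_raw_norm_near_one_g_when_still_and_calibrated(self, participant, profiles):
        t = generate_trial(participant, profiles["LD"], seed=55)
        # settle-in interval: gravity only, no activity yet
        settle = t.raw_left[: 10 * 30]
        norms = np.linalg.norm(settle, axis=1)
        assert abs(np.median(norms) - 1.0) < 0.01

    def test_calibration_error_distorts_raw(self, participant, profiles):
        err = CalibrationError(gain=(1.05, 0.95, 1.02), offset=(0.02, -0.03, 0.0))
        clean = generate_trial(participant, profiles["LD"], seed=9)
        dirty = generate_trial(participant, profiles["LD"], seed=9, err=err)
        expected = clean.raw_left * np.array(err.gain) + np.array(err.offset)
        np.testing.assert_allclose(dirty.raw_left, expected, atol=1e-12)

    def test_calibration_error_bounds_enforced(self):
        with pytest.raises(ValueError):
            CalibrationError(gain=(1.2, 1.0, 1.0))
        with pytest.raises(ValueError):
            CalibrationError(offset=(0.2, 0.0, 0.0))


class TestGenerateCohort:
    def test_default_cohort_schedules_all_trials(self, default_cohort):
        assert default_cohort.n_scheduled == 18 * 12

    def test_exclusion_count_plausible(self, default_cohort):
        # Binomial(216, 34/216): mean 34, 3 sigma ~ 16
        n_excl = default_cohort.n_scheduled - len(default_cohort.retained)
        assert 18 <= n_excl <= 50

    def test_zero_dropout_keeps_everything(self):
        ds = generate_cohort(RunConfig(n_participants=1, dropout=0.0), seed=5)
        assert len(ds.retained) == ds.n_scheduled == 12

    def test_cohort_deterministic(self, small_cohort):
        again = generate_cohort(RunConfig(n_participants=2), seed=11)
        assert [t.exclusion_flag for t in again.trials] == \
            [t.exclusion_flag for t in small_cohort.trials]
        np.testing.assert_array_equal(again.trials[0].raw_right,
                                      small_cohort.trials[0].raw_right)
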