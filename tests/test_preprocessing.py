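"""Windowing, exclusion filters, gait extraction, padding, resampling and
normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imugrf.data import IMUTrial, WindowSet
from imugrf.errors import AnnotationError, LengthError, ValidationError
from imugrf.preprocessing import (
    WindowNormalizer,
    WindowingConfig,
    apply_normalizer,
    extract_gait_windows,
    filter_outliers,
    filter_still,
    fit_normalizer,
    pad_trial_to_window,
    resample_trial,
    segment_windows,
    stillness_statistic,
)

from conftest import random_window_set


def trial_of(data, fs=100.0, grf=None, onsets=None):
    return IMUTrial(participant_id="P0", sampling_rate=fs, data=data,
                    grf=grf, stance_onsets=onsets, trial_id="t")


class TestSegmentWindows:
    @pytest.mark.parametrize("n_steps,expected_starts", [
        (128, [0]),
        (256, [0, 64, 128]),
        (127, []),
        (6000, list(range(0, 5873, 64))),
    ])
    def test_window_count_formula(self, rng, n_steps, expected_starts):
        ws = segment_windows(trial_of(rng.normal(size=(n_steps, 48))))
        assert list(ws.starts) == expected_starts
        if n_steps >= 128:
            assert len(ws) == (n_steps - 128) // 64 + 1

    def test_grf_sliced_alongside(self, rng):
        data = rng.normal(size=(256, 48))
        grf = rng.normal(size=(256, 3))
        ws = segment_windows(trial_of(data, grf=grf))
        np.testing.assert_array_equal(ws.grf[1], grf[64:192])

    def test_spans_cover_trial_prefix(self, rng):
        n = 500
        ws = segment_windows(trial_of(rng.normal(size=(n, 48))))
        covered = np.zeros(n, dtype=bool)
        for s in ws.starts:
            covered[s : s + 128] = True
        k = len(ws)
        assert covered[: 64 * (k - 1) + 128].all()
        assert not covered[64 * (k - 1) + 128 :].any()


class TestStillnessFilter:
    def test_constant_window_removed(self):
        ws = random_window_set(np.random.default_rng(0), n=1)
        ws.data[:] = 3.0
        assert len(filter_still(ws)) == 0

    def test_boundary_statistic_retained(self):
        """One accelerometer axis with std exactly 4.8 m/s², 23 constant:
        statistic is 4.8/24 = 0.2, retained under the >= comparison."""
        ws = random_window_set(np.random.default_rng(0), n=1)
        ws.data[:] = 0.0
        ws.data[0, ::2, 0] = 4.8
        ws.data[0, 1::2, 0] = -4.8
        assert stillness_statistic(ws)[0] == pytest.approx(0.2, abs=1e-12)
        assert len(filter_still(ws, threshold=0.2)) == 1

    def test_moving_signal_retained(self):
        ws = random_window_set(np.random.default_rng(0), n=1)
        t = np.arange(128)
        ws.data[0, :, :] = 5 * np.sin(0.3 * t)[:, None]
        assert len(filter_still(ws)) == 1


class TestOutlierFilter:
    def test_acceleration_spike_removed(self):
        ws = random_window_set(np.random.default_rng(0), n=2)
        ws.data[0, 5, 2] = 161.0
        out = filter_outliers(ws)
        assert len(out) == 1 and out.trial_ids[0] == "T1"

    def test_values_exactly_at_threshold_retained(self):
        ws = random_window_set(np.random.default_rng(0), n=1)
        ws.data[0, :, 0:3] = 160.0
        ws.data[0, :, 3:6] = 2000.0
        assert len(filter_outliers(ws)) == 1

    def test_gyro_spike_removed(self):
        ws = random_window_set(np.random.default_rng(0), n=1)
        ws.data[0, 99, 5] = 2500.0  # a gyroscope column
        assert len(filter_outliers(ws)) == 0

    def test_filter_order_independent(self, rng):
        ws = random_window_set(rng, n=8)
        ws.data[1] = 0.0                      # still
        ws.data[3, 0, 0] = 500.0              # acc outlier
        ws.data[5, 2, 4] = 3000.0             # gyro outlier
        a = filter_outliers(filter_still(ws))
        b = filter_still(filter_outliers(ws))
        assert list(a.trial_ids) == list(b.trial_ids)
        np.testing.assert_array_equal(a.data, b.data)


class TestGaitWindows:
    def test_offset_arithmetic(self, rng):
        trial = trial_of(rng.normal(size=(300, 48)), onsets=np.array([100]))
        ws = extract_gait_windows(trial)
        assert list(ws.starts) == [60]
        np.testing.assert_array_equal(ws.data[0], trial.data[60:188])

    def test_early_onset_clamped(self, rng):
        trial = trial_of(rng.normal(size=(300, 48)), onsets=np.array([20]))
        assert list(extract_gait_windows(trial).starts) == [0]

    def test_overrunning_window_dropped(self, rng):
        trial = trial_of(rng.normal(size=(300, 48)), onsets=np.array([250]))
        assert len(extract_gait_windows(trial)) == 0

    def test_missing_annotations_rejected(self, rng):
        with pytest.raises(AnnotationError):
            extract_gait_windows(trial_of(rng.normal(size=(300, 48))))


class TestPadding:
    def test_drop_landing_trial_padded(self, rng):
        trial = trial_of(rng.normal(size=(80, 48)), grf=rng.normal(size=(80, 3)))
        w = pad_trial_to_window(trial)
        assert w.valid_length == 80
        assert np.all(w.data[80:] == 0) and np.all(w.grf[80:] == 0)

    def test_full_length_trial_unchanged(self, rng):
        data = rng.normal(size=(128, 48))
        w = pad_trial_to_window(trial_of(data))
        assert w.valid_length == 128
        np.testing.assert_array_equal(w.data, data)

    def test_too_long_trial_rejected(self, rng):
        with pytest.raises(LengthError):
            pad_trial_to_window(trial_of(rng.normal(size=(129, 48))))


class TestResample:
    def test_sample_count_200_to_100(self, rng):
        trial = trial_of(rng.normal(size=(256, 48)), fs=200.0,
                         grf=rng.normal(size=(256, 3)))
        out = resample_trial(trial, 100.0)
        assert out.n_steps == 128 and out.sampling_rate == 100.0
        assert out.grf.shape == (128, 3)

    def test_linear_ramp_is_fixed_point(self):
        data = np.tile(np.arange(240.0)[:, None], (1, 48))
        out = resample_trial(trial_of(data, fs=120.0), 100.0)
        expected = np.arange(out.n_steps) * 120.0 / 100.0
        np.testing.assert_allclose(out.data[:, 0], expected, atol=1e-9)

    def test_same_rate_is_identity(self, rng):
        trial = trial_of(rng.normal(size=(100, 48)))
        assert resample_trial(trial, 100.0) is trial


class TestNormalization:
    def test_zscore_definition(self, rng):
        ws = random_window_set(rng, n=20, with_grf=True)
        ws.data[:, :, 0] = ws.data[:, :, 0] * 2.0 + 5.0
        stats = fit_normalizer(ws)
        assert stats.imu_mean[0] == pytest.approx(5.0, abs=0.5)
        out = apply_normalizer(ws, stats)
        flat = out.data.reshape(-1, 48)
        assert np.abs(flat.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-6)

    def test_constant_axis_maps_to_zero(self, rng):
        ws = random_window_set(rng, n=4)
        ws.data[:, :, 7] = 2.5
        out = apply_normalizer(ws, fit_normalizer(ws))
        np.testing.assert_array_equal(out.data[:, :, 7], 0.0)

    def test_round_trip_exact(self, rng):
        ws = random_window_set(rng, n=10, with_grf=True)
        stats = fit_normalizer(ws)
        back = apply_normalizer(apply_normalizer(ws, stats), stats, invert=True)
        assert np.abs(back.data - ws.data).max() < 1e-10
        assert np.abs(back.grf - ws.grf).max() < 1e-10

    def test_two_pass_oracle_agreement(self, rng):
        """Statistics agree with a brute-force two-pass mean/std over the
        valid rows within 1e-10."""
        ws = random_window_set(rng, n=7, with_grf=True,
                               valid_lengths=[128, 80, 128, 60, 128, 100, 128])
        stats = fit_normalizer(ws)
        rows = np.concatenate([ws.data[i, : ws.valid_lengths[i]]
                               for i in range(len(ws))])
        mean = rows.sum(axis=0) / len(rows)
        std = np.sqrt(((rows - mean) ** 2).sum(axis=0) / len(rows))
        assert np.abs(stats.imu_mean - mean).max() < 1e-10
        assert np.abs(stats.imu_std - np.maximum(std, 1e-8)).max() < 1e-10

    def test_padded_rows_stay_zero(self, rng):
        ws = random_window_set(rng, n=3, with_grf=True, valid_lengths=[50, 128, 90])
        out = WindowNormalizer().fit(ws).transform(ws)
        assert np.all(out.data[0, 50:] == 0)
        assert np.all(out.grf[2, 90:] == 0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
    def test_roundtrip_property(self, n, seed):
        ws = random_window_set(np.random.default_rng(seed), n=n)
        stats = fit_normalizer(ws)
        back = apply_normalizer(apply_normalizer(ws, stats), stats, invert=True)
        assert np.abs(back.data - ws.data).max() < 1e-10


def test_windowing_config_validation():
    with pytest.raises(ValidationError):
        WindowingConfig(overlap=1.0)
    with pytest.raises(ValidationError):
        WindowingConfig(acc_max=0.0)
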