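"""Metrics, phase masking, folds, spectrum analysis, scaling grids, and
significance testing."""

import numpy as np
import pytest

from imugrf.data import WindowSet
from imugrf.errors import ValidationError
from imugrf.evaluation import (
    compare_models,
    evaluate_predictions,
    exponential_fraction_grid,
    linear_fraction_grid,
    make_folds,
    pearson_r,
    phase_mask,
    rmse,
    rrmse,
    scaling_curve,
    spectrum_error,
    subsample_indices,
)

from conftest import random_window_set


class TestPhaseMask:
    def test_boundary_value_included(self):
        v = np.array([0.1961, 0.1962, 0.1963, 0.0])
        np.testing.assert_array_equal(phase_mask(v), [False, True, True, False])

    def test_padded_rows_always_excluded(self):
        v = np.full(10, 5.0)
        valid = np.array([True] * 6 + [False] * 4)
        assert phase_mask(v, valid).sum() == 6

    def test_all_swing_gives_empty_mask(self):
        assert phase_mask(np.zeros(50)).sum() == 0


class TestScalarMetrics:
    def test_identity_and_antisymmetry(self, rng):
        a = rng.normal(size=100)
        assert pearson_r(a, a) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)
        assert rmse(a, a) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([0, 1, 2], [0, 1, 4]) == pytest.approx(np.sqrt(4 / 3), abs=1e-12)

    def test_two_pass_oracle(self, rng):
        """Pearson and RMSE agree with textbook two-pass formulas to 1e-10."""
        a, b = rng.normal(size=300), rng.normal(size=300)
        am, bm = a.mean(), b.mean()
        cov = ((a - am) * (b - bm)).sum() / len(a)
        oracle_r = cov / (a.std() * b.std())
        assert pearson_r(a, b) == pytest.approx(oracle_r, abs=1e-10)
        assert rmse(a, b) == pytest.approx(np.sqrt(((a - b) ** 2).mean()), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r(np.ones(10), np.arange(10))

    def test_rrmse_formula_and_scale_invariance(self, rng):
        assert rrmse(0.1, np.array([0.0, 2.0])) == pytest.approx(5.0)
        gold = rng.uniform(0, 2, size=200)
        est = gold + rng.normal(0, 0.1, size=200)
        r1 = rrmse(rmse(est, gold), gold)
        c = 3.7
        r2 = rrmse(rmse(c * est, c * gold), c * gold)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_rrmse_zero_range_rejected(self):
        with pytest.raises(ValidationError):
            rrmse(0.1, np.ones(5))


class TestEvaluatePredictions:
    def _labeled(self, rng, n=6):
        ws = random_window_set(rng, n=n, with_grf=True)
        # make vGRF a plausible stance signal
        t = np.arange(128)
        for i in range(n):
            ws.grf[i, :, 2] = 6 * np.clip(np.sin(2 * np.pi * t / 64), 0, None) + \
                rng.normal(0, 0.2, 128)
        return ws

    def test_perfect_prediction(self, rng):
        ws = self._labeled(rng)
        rep = evaluate_predictions(ws.grf.copy(), ws)
        for pid, rho in rep.correlations.items():
            np.testing.assert_allclose(rho, 1.0, atol=1e-12)
            np.testing.assert_allclose(rep.rmses[pid], 0.0, atol=1e-12)
            assert rep.peak_rrmses[pid] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_preserves_correlation(self, rng):
        ws = self._labeled(rng)
        rep = evaluate_predictions(ws.grf + 0.1, ws)
        for pid in rep.correlations:
            np.testing.assert_allclose(rep.correlations[pid], 1.0, atol=1e-9)
            np.testing.assert_allclose(rep.rmses[pid], 0.1, atol=1e-9)
            assert rep.peak_rmses[pid] == pytest.approx(0.1, abs=1e-9)

    def test_appended_flight_windows_do_not_change_metrics(self, rng):
        """Appending all-flight (zero-GRF) windows leaves every per-
        participant metric exactly unchanged."""
        ws = self._labeled(rng)
        est = ws.grf + rng.normal(0, 0.3, size=ws.grf.shape)
        rep1 = evaluate_predictions(est, ws)

        flight = random_window_set(rng, n=3, with_grf=True)
        flight.grf[:] = 0.0
        ws2 = WindowSet.concatenate([ws, flight])
        est2 = np.concatenate([est, rng.normal(size=(3, 128, 3))])
        rep2 = evaluate_predictions(est2, ws2)
        for pid in rep1.correlations:
            np.testing.assert_array_equal(rep1.correlations[pid],
                                          rep2.correlations[pid])
            np.testing.assert_array_equal(rep1.rmses[pid], rep2.rmses[pid])
            assert rep1.peak_rmses[pid] == rep2.peak_rmses[pid]


class TestSpectrum:
    def test_identical_signals_zero_curve(self, rng):
        w = rng.normal(size=(10, 128))
        freqs, err = spectrum_error(w, w)
        assert len(freqs) == 65
        assert freqs[-1] == 50.0
        np.testing.assert_array_equal(err, 0.0)

    def test_pure_tone_concentrates_at_its_bin(self, rng):
        gold = rng.normal(size=(4, 128), scale=0.01)
        t = np.arange(128) / 100.0
        est = gold + 2.0 * np.sin(2 * np.pi * 5.0 * t)  # 5 Hz extra tone
        freqs, err = spectrum_error(est, gold)
        assert freqs[np.argmax(np.abs(err))] == pytest.approx(5.0, abs=0.4)

    def test_modes(self, rng):
        a, b = rng.normal(size=(3, 128)), rng.normal(size=(3, 128))
        _, signed = spectrum_error(a, b, mode="signed")
        _, absolute = spectrum_error(a, b, mode="absolute")
        assert np.all(absolute >= 0)
        assert np.any(signed < 0)
        with pytest.raises(ValidationError):
            spectrum_error(a, b, mode="nonsense")


class TestFolds:
    def test_fifteen_participants_five_folds_of_three(self):
        ids = [f"P{i}" for i in range(15)]
        folds = make_folds(ids, k=5, seed=0)
        sizes = np.bincount(list(folds.values()))
        np.testing.assert_array_equal(sizes, [3, 3, 3, 3, 3])

    def test_seventeen_participants_balanced_remainder(self):
        folds = make_folds([f"P{i}" for i in range(17)], k=5, seed=1)
        sizes = sorted(np.bincount(list(folds.values())), reverse=True)
        assert sizes == [4, 4, 3, 3, 3]

    def test_seeded_determinism_and_partition(self):
        ids = [f"P{i}" for i in range(11)]
        a = make_folds(ids, seed=5)
        b = make_folds(ids, seed=5)
        assert a == b
        assert set(a) == set(ids)

    def test_too_few_participants(self):
        with pytest.raises(ValidationError):
            make_folds(["P0", "P1"], k=5)


class TestScaling:
    def test_fraction_grids(self):
        lin = linear_fraction_grid()
        exp = exponential_fraction_grid()
        assert len(lin) == 10 and lin[0] == 1.0 and lin[-1] == pytest.approx(0.1)
        assert len(exp) == 11 and exp[0] == 1.0
        assert exp[-1] == pytest.approx(0.01)

    def test_full_fraction_uses_everything(self, rng):
        ws = random_window_set(rng, n=12)
        seen = {}
        scaling_curve(ws, [1.0], seed=0,
                      train_and_eval=lambda s: seen.setdefault("n", len(s)) or 0.0)
        assert seen["n"] == 12

    def test_nested_subsamples(self):
        big = set(subsample_indices(100, 0.5, seed=4))
        small = set(subsample_indices(100, 0.1, seed=4))
        assert small <= big

    def test_unsorted_fractions_rejected(self, rng):
        ws = random_window_set(rng, n=5)
        with pytest.raises(ValidationError):
            scaling_curve(ws, [0.1, 1.0], seed=0, train_and_eval=lambda s: 0.0)


class TestCompareModels:
    def test_identical_columns_no_tests_run(self, rng):
        col = rng.normal(size=8)
        p, pairs = compare_models(np.column_stack([col, col, col]))
        assert p == 1.0 and pairs == {}

    def test_two_settings_single_comparison(self, rng):
        a = rng.normal(size=10)
        b = a + 2.0 + rng.normal(0, 0.1, size=10)
        p, pairs = compare_models(np.column_stack([a, b]))
        assert p < 0.05 and list(pairs) == [(0, 1)]

    def test_four_settings_six_comparisons(self, rng):
        base = rng.normal(size=12)
        m = np.column_stack([base + k for k in (0.0, 1.0, 2.0, 3.0)])
        m += rng.normal(0, 0.05, size=m.shape)
        p, pairs = compare_models(m)
        assert p < 0.05 and len(pairs) == 6
        assert all(0 <= v <= 1 for v in pairs.values())

    def test_missing_entries_rejected(self):
        m = np.ones((4, 2))
        m[0, 0] = np.nan
        with pytest.raises(ValidationError):
            compare_models(m)
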