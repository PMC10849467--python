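"""Evaluation: stance-phase masking, accuracy metrics, subject-wise
cross-validation, spectrum analysis, scaling curves, and significance tests.

Metrics follow the standard protocol for mass-normalized GRF estimation:
swing/flight samples where gold vGRF falls below 2% of body weight
(0.02·9.81 N/kg, mass-free because GRF is stored in N/kg) are excluded;
Pearson ρ and RMSE are computed per participant over all included samples
concatenated; rRMSE normalizes RMSE by the participant's gold vGRF range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sstats

from .data import WindowSet
from .errors import ValidationError

logger = logging.getLogger(__name__)

BODY_WEIGHT_NKG = 9.81          # weight per unit mass
STANCE_THRESHOLD_FRACTION = 0.02
VGRF_AXIS = 2                   # columns are (ml, ap, v)


@dataclass(frozen=True)
class EvalConfig:
    stance_threshold_fraction: float = STANCE_THRESHOLD_FRACTION
    n_folds: int = 5
    significance_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.stance_threshold_fraction <= 1:
            raise ValidationError("stance_threshold_fraction outside (0, 1]")
        if self.n_folds < 2:
            raise ValidationError("need at least 2 folds")


def linear_fraction_grid() -> np.ndarray:
    """100%, 90%, …, 10% — ten points."""
    return np.round(np.arange(1.0, 0.05, -0.1), 10)


def exponential_fraction_grid() -> np.ndarray:
    """10⁰, 10⁻⁰·², …, 10⁻² — eleven points."""
    return 10.0 ** (-0.2 * np.arange(11))


# ---------------------------------------------------------------------------
# phase masking and scalar metrics
# ---------------------------------------------------------------------------

def phase_mask(gold_vgrf: np.ndarray,
               valid: np.ndarray | None = None,
               threshold_fraction: float = STANCE_THRESHOLD_FRACTION) -> np.ndarray:
    """True exactly where gold vGRF ≥ threshold_fraction·9.81 N/kg (stance
    or landing); padded rows (``valid`` False) are always excluded."""
    mask = np.asarray(gold_vgrf) >= threshold_fraction * BODY_WEIGHT_NKG
    if valid is not None:
        mask = mask & np.asarray(valid, dtype=bool)
    return mask


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("pearson_r needs two equal-length sequences, n >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("pearson_r undefined for a zero-variance input")
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("rmse needs equal-length sequences")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rrmse(rmse_value: float, gold: np.ndarray) -> float:
    """RMSE divided by the participant's global gold range, as a percent."""
    gold = np.asarray(gold, dtype=float).ravel()
    rng = gold.max() - gold.min()
    if rng <= 0:
        raise ValidationError("rrmse undefined for zero gold range")
    return float(rmse_value / rng * 100.0)


# ---------------------------------------------------------------------------
# per-participant evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-participant accuracy of a fitted GRF estimator.

    ``correlations``/``rmses`` map participant → length-3 array (ml, ap, v);
    peak metrics are per participant on per-window vGRF peaks.
    """

    correlations: dict[str, np.ndarray] = field(default_factory=dict)
    rmses: dict[str, np.ndarray] = field(default_factory=dict)
    peak_correlations: dict[str, float] = field(default_factory=dict)
    peak_rmses: dict[str, float] = field(default_factory=dict)
    peak_rrmses: dict[str, float] = field(default_factory=dict)
    spectrum_error_curve: np.ndarray | None = None
    spectrum_freqs: np.ndarray | None = None
    fold_map: dict[str, int] = field(default_factory=dict)

    def mean_correlation(self, axis: int = VGRF_AXIS) -> float:
        return float(np.mean([c[axis] for c in self.correlations.values()]))

    def to_dict(self) -> dict:
        return {
            "correlations": {k: list(v) for k, v in self.correlations.items()},
            "rmses": {k: list(v) for k, v in self.rmses.items()},
            "peak_correlations": self.peak_correlations,
            "peak_rmses": self.peak_rmses,
            "peak_rrmses": self.peak_rrmses,
            "spectrum_error_curve": (
                None if self.spectrum_error_curve is None
                else np.asarray(self.spectrum_error_curve).tolist()
            ),
            "fold_map": self.fold_map,
        }


def evaluate_predictions(est: np.ndarray, ws: WindowSet,
                         cfg: EvalConfig | None = None) -> EvalReport:
    """Per-participant ρ/RMSE per GRF axis plus peak-vGRF metrics.

    *est* is (n_windows, 128, 3) in N/kg aligned with the labeled *ws*.
    Included samples of each participant are concatenated before computing
    ρ/RMSE; windows whose phase mask is empty are skipped for peak metrics.
    """
    cfg = cfg or EvalConfig()
    if not ws.has_grf:
        raise ValidationError("evaluation requires gold GRF labels")
    est = np.asarray(est, dtype=float)
    if est.shape != ws.grf.shape:
        raise ValidationError("prediction shape does not match labels")
    report = EvalReport()
    valid = ws.valid_mask()
    for pid in sorted(set(ws.participant_ids)):
        sel = ws.participant_ids == pid
        gold = ws.grf[sel]
        pred = est[sel]
        mask = phase_mask(gold[:, :, VGRF_AXIS], valid[sel],
                          cfg.stance_threshold_fraction)
        if mask.sum() < 2:
            logger.warning("participant %s: no stance samples, skipped", pid)
            continue
        rho = np.array([pearson_r(pred[:, :, k][mask], gold[:, :, k][mask])
                        for k in range(3)])
        err = np.array([rmse(pred[:, :, k][mask], gold[:, :, k][mask])
                        for k in range(3)])
        report.correlations[str(pid)] = rho
        report.rmses[str(pid)] = err
        # per-window vGRF peaks over included samples
        gold_peaks, est_peaks = [], []
        for w in range(gold.shape[0]):
            m = mask[w]
            if not m.any():
                logger.info("participant %s window %d all-swing, skipped", pid, w)
                continue
            gold_peaks.append(gold[w, :, VGRF_AXIS][m].max())
            est_peaks.append(pred[w, :, VGRF_AXIS][m].max())
        if len(gold_peaks) >= 2 and np.std(gold_peaks) > 0 and np.std(est_peaks) > 0:
            report.peak_correlations[str(pid)] = pearson_r(est_peaks, gold_peaks)
        peak_rmse = rmse(est_peaks, gold_peaks)
        report.peak_rmses[str(pid)] = peak_rmse
        report.peak_rrmses[str(pid)] = rrmse(peak_rmse,
                                             gold[:, :, VGRF_AXIS][mask])
    return report


def peak_vgrf_metrics(est: np.ndarray, ws: WindowSet,
                      cfg: EvalConfig | None = None) -> dict[str, dict[str, float]]:
    """Per-participant ρ/RMSE/rRMSE over paired per-window vGRF peaks."""
    report = evaluate_predictions(est, ws, cfg)
    return {
        pid: {
            "rho": report.peak_correlations.get(pid, float("nan")),
            "rmse": report.peak_rmses[pid],
            "rrmse": report.peak_rrmses[pid],
        }
        for pid in report.peak_rmses
    }


# ---------------------------------------------------------------------------
# spectrum analysis
# ---------------------------------------------------------------------------

def spectrum_error(est: np.ndarray, gold: np.ndarray, fs: float = 100.0,
                   mode: str = "signed") -> tuple[np.ndarray, np.ndarray]:
    """Mean per-frequency error between estimated and gold GRF windows.

    Per window the one-sided FFT magnitude spectrum of the estimate minus
    that of the gold signal ("signed", default), its absolute value
    ("absolute"), or the magnitude of the complex difference ("complex");
    averaged across windows.  Returns (frequencies, mean error curve).
    """
    est = np.asarray(est, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if est.shape != gold.shape:
        raise ValidationError("windows of unequal shape")
    fe = np.fft.rfft(est, axis=1)
    fg = np.fft.rfft(gold, axis=1)
    if mode == "signed":
        diff = np.abs(fe) - np.abs(fg)
    elif mode == "absolute":
        diff = np.abs(np.abs(fe) - np.abs(fg))
    elif mode == "complex":
        diff = np.abs(fe - fg)
    else:
        raise ValidationError(f"unknown spectrum mode {mode!r}")
    freqs = np.fft.rfftfreq(est.shape[1], d=1.0 / fs)
    return freqs, diff.mean(axis=0)


# ---------------------------------------------------------------------------
# cross-validation, scaling curves, statistics
# ---------------------------------------------------------------------------

def make_folds(participant_ids: Sequence[str], k: int = 5,
               seed: int | None = 0) -> dict[str, int]:
    """Random participant-level partition into *k* folds whose sizes differ
    by at most one; seeded and deterministic."""
    ids = list(dict.fromkeys(participant_ids))     # unique, order-preserving
    if len(ids) < k:
        raise ValidationError(f"{len(ids)} participants < {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = np.array_split(order, k)
    out: dict[str, int] = {}
    for f, members in enumerate(folds):
        for m in members:
            out[ids[m]] = f
    return out


def cross_validate(ws: WindowSet, fit_predict: Callable[[WindowSet, WindowSet], np.ndarray],
                   k: int = 5, seed: int = 0,
                   cfg: EvalConfig | None = None) -> EvalReport:
    """Subject-wise k-fold CV: *fit_predict(train, test)* returns predictions
    for the test windows; per-participant metrics are pooled across folds."""
    fold_map = make_folds(list(ws.participant_ids), k=k, seed=seed)
    merged = EvalReport(fold_map=fold_map)
    for f in range(k):
        test_sel = np.array([fold_map[str(p)] == f for p in ws.participant_ids])
        train, test = ws[~test_sel], ws[test_sel]
        pred = fit_predict(train, test)
        rep = evaluate_predictions(pred, test, cfg)
        merged.correlations.update(rep.correlations)
        merged.rmses.update(rep.rmses)
        merged.peak_correlations.update(rep.peak_correlations)
        merged.peak_rmses.update(rep.peak_rmses)
        merged.peak_rrmses.update(rep.peak_rrmses)
    return merged


def scaling_curve(train: WindowSet, fractions: Sequence[float],
                  seed: int,
                  train_and_eval: Callable[[WindowSet], float]) -> list[tuple[float, float]]:
    """Metric as a function of the labeled-training fraction.

    Windows are subsampled with nesting (the windows used at a smaller
    fraction are a subset of those at any larger one), by taking prefixes of
    one seeded permutation.  *train_and_eval* maps a training subset to a
    scalar metric.
    """
    fractions = list(fractions)
    if any(fractions[i] < fractions[i + 1] for i in range(len(fractions) - 1)):
        raise ValidationError("fractions must be sorted descending")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    out = []
    for frac in fractions:
        n = int(round(frac * len(train)))
        if n == 0:
            raise ValidationError(f"fraction {frac} yields zero training windows")
        subset = train[np.sort(order[:n])]
        out.append((float(frac), float(train_and_eval(subset))))
    return out


def subsample_indices(n: int, fraction: float, seed: int) -> np.ndarray:
    """Seeded nested subsample of range(n) (prefix of one permutation)."""
    k = int(round(fraction * n))
    if k == 0:
        raise ValidationError(f"fraction {fraction} yields zero windows")
    return np.sort(np.random.default_rng(seed).permutation(n)[:k])


def compare_models(metric_matrix: np.ndarray, alpha: float = 0.05
                   ) -> tuple[float, dict[tuple[int, int], float]]:
    """One-way ANOVA across model settings (columns) over participants
    (rows); if significant, all pairwise paired t-tests with Bonferroni
    correction (p × number of comparisons, capped at 1)."""
    m = np.asarray(metric_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValidationError("need >= 2 settings and >= 3 participants")
    if np.isnan(m).any():
        raise ValidationError("metric matrix has missing entries")
    if np.allclose(m, m[:, [0]]):
        return 1.0, {}
    _, p_anova = sstats.f_oneway(*[m[:, j] for j in range(m.shape[1])])
    pairwise: dict[tuple[int, int], float] = {}
    if p_anova < alpha:
        pairs = list(combinations(range(m.shape[1]), 2))
        for i, j in pairs:
            _, p = sstats.ttest_rel(m[:, i], m[:, j])
            pairwise[(i, j)] = min(1.0, float(p) * len(pairs))
    return float(p_anova), pairwise
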