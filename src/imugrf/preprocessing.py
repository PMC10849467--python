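"""Windowing, exclusion filters, resampling, gait-window extraction,
zero-padding, and per-axis normalization.

Continuous trials are cut into 128-sample windows with 50% overlap; stillness
windows (mean over the 24 accelerometer axes of the per-axis standard
deviation below 0.2 m/s²) and outlier windows (any |acc| > 160 m/s² or
|gyro| > 2000 deg/s) are excluded.  Labeled gait trials are windowed from 40
samples before each stance onset; short drop-landing trials are zero-padded
to 128 samples.  Threshold comparisons are strict: a value exactly at a
threshold is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import (
    WINDOW_LENGTH,
    IMUTrial,
    IMUWindow,
    NormalizationStats,
    WindowSet,
)
from .errors import AnnotationError, LengthError, ValidationError
from .layout import ACC_COLUMNS, GYR_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowingConfig:
    """Thresholds and geometry of the windowing pipeline (units in field
    names' docs): 1.28 s windows with 50% overlap at 100 Hz."""

    window_length: int = WINDOW_LENGTH
    overlap: float = 0.5
    stillness_threshold: float = 0.2      # m/s², mean of per-axis acc std
    acc_max: float = 160.0                # m/s²
    gyro_max: float = 2000.0              # deg/s
    pre_stance_offset: int = 40           # samples before stance onset

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValidationError(f"overlap {self.overlap} outside [0, 1)")
        for name in ("stillness_threshold", "acc_max", "gyro_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def hop(self) -> int:
        return int(round(self.window_length * (1 - self.overlap)))


def segment_windows(trial: IMUTrial, cfg: WindowingConfig | None = None) -> WindowSet:
    """Cut a continuous trial into overlapping fixed-length windows.

    Starts are 0, hop, 2·hop, …; the count is ``floor((n − L)/hop) + 1`` for
    ``n ≥ L`` and zero otherwise (trailing remainder discarded).  GRF is
    sliced alongside when present.
    """
    cfg = cfg or WindowingConfig()
    L, hop = cfg.window_length, cfg.hop
    n = trial.n_steps
    if n < L:
        return WindowSet.empty(with_grf=trial.grf is not None)
    starts = np.arange(0, n - L + 1, hop)
    windows = [
        IMUWindow(
            data=trial.data[s : s + L].copy(),
            grf=None if trial.grf is None else trial.grf[s : s + L].copy(),
            participant_id=trial.participant_id,
            trial_id=trial.trial_id,
            start=int(s),
        )
        for s in starts
    ]
    return WindowSet.from_windows(windows)


def stillness_statistic(ws: WindowSet) -> np.ndarray:
    """Mean over the 24 accelerometer axes of the per-axis standard deviation,
    per window, computed over valid (non-padded) rows only."""
    out = np.empty(len(ws))
    for i in range(len(ws)):
        rows = ws.data[i, : ws.valid_lengths[i], :][:, ACC_COLUMNS]
        out[i] = rows.std(axis=0).mean()
    return out


def filter_still(ws: WindowSet, threshold: float = 0.2) -> WindowSet:
    """Drop still windows: retained iff the stillness statistic ≥ threshold."""
    stat = stillness_statistic(ws)
    keep = stat >= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_still removed %d of %d windows", removed, len(ws))
    return ws[keep]


def filter_outliers(
    ws: WindowSet, acc_max: float = 160.0, gyro_max: float = 2000.0
) -> WindowSet:
    """Drop windows containing any |acc| > acc_max or |gyro| > gyro_max
    (strict inequality: values exactly at the threshold are retained)."""
    acc_peak = np.abs(ws.data[:, :, ACC_COLUMNS]).max(axis=(1, 2)) if len(ws) else np.empty(0)
    gyr_peak = np.abs(ws.data[:, :, GYR_COLUMNS]).max(axis=(1, 2)) if len(ws) else np.empty(0)
    keep = (acc_peak <= acc_max) & (gyr_peak <= gyro_max)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_outliers removed %d of %d windows", removed, len(ws))
    return ws[keep]


def extract_gait_windows(trial: IMUTrial, cfg: WindowingConfig | None = None) -> WindowSet:
    """One window per stance onset, starting ``pre_stance_offset`` samples
    before it (clamped at 0); windows overrunning the trial end are dropped."""
    cfg = cfg or WindowingConfig()
    if trial.stance_onsets is None or len(trial.stance_onsets) == 0:
        raise AnnotationError(
            f"trial {trial.trial_id!r} has no stance-onset annotations"
        )
    L = cfg.window_length
    windows = []
    for onset in np.asarray(trial.stance_onsets, dtype=int):
        start = max(0, onset - cfg.pre_stance_offset)
        if start + L > trial.n_steps:
            continue
        windows.append(
            IMUWindow(
                data=trial.data[start : start + L].copy(),
                grf=None if trial.grf is None else trial.grf[start : start + L].copy(),
                participant_id=trial.participant_id,
                trial_id=trial.trial_id,
                start=start,
            )
        )
    if not windows:
        return WindowSet.empty(with_grf=trial.grf is not None)
    return WindowSet.from_windows(windows)


def pad_trial_to_window(trial: IMUTrial, target: int = WINDOW_LENGTH) -> IMUWindow:
    """Zero-pad a short trial (e.g. an 80-step drop landing) to the model's
    fixed input length, recording the true length in ``valid_length``."""
    n = trial.n_steps
    if n > target:
        raise LengthError(f"trial has {n} steps, longer than target {target}")
    data = np.zeros((target, trial.data.shape[1]))
    data[:n] = trial.data
    grf = None
    if trial.grf is not None:
        grf = np.zeros((target, 3))
        grf[:n] = trial.grf
    return IMUWindow(
        data=data,
        grf=grf,
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
        start=0,
        valid_length=n,
    ).validate()


def resample_trial(trial: IMUTrial, fs_out: float = 100.0) -> IMUTrial:
    """Linearly resample IMU (and GRF) onto a uniform *fs_out* grid covering
    the same duration; identity when rates already match."""
    fs_in = trial.sampling_rate
    if fs_out == fs_in:
        return trial
    if fs_out > fs_in:
        raise ValidationError(
            f"refusing to upsample from {fs_in} Hz to {fs_out} Hz"
        )
    n_in = trial.n_steps
    duration = (n_in - 1) / fs_in
    n_out = int(np.floor(duration * fs_out)) + 1
    t_in = np.arange(n_in) / fs_in
    t_out = np.arange(n_out) / fs_out
    data = np.column_stack(
        [np.interp(t_out, t_in, trial.data[:, j]) for j in range(trial.data.shape[1])]
    )
    grf = None
    if trial.grf is not None:
        grf = np.column_stack([np.interp(t_out, t_in, trial.grf[:, j]) for j in range(3)])
    onsets = None
    if trial.stance_onsets is not None:
        onsets = np.unique(
            np.round(np.asarray(trial.stance_onsets) * fs_out / fs_in).astype(int)
        )
        onsets = onsets[onsets < n_out]
    return IMUTrial(
        participant_id=trial.participant_id,
        sampling_rate=fs_out,
        data=data,
        grf=grf,
        stance_onsets=onsets,
        trial_id=trial.trial_id,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class WindowNormalizer(TransformerMixin, BaseEstimator):
    """Per-axis z-scoring of IMU (and GRF) windows.

    Statistics are computed over all valid (non-padded) rows of the fitted
    window set; standard deviations below ``epsilon`` are clamped so constant
    axes map to zero.  ``inverse_transform`` undoes the scaling exactly.

    Attributes
    ----------
    stats_ : NormalizationStats
        Fitted per-axis means and clamped standard deviations.
    """

    def __init__(self, epsilon: float = 1e-8, with_grf: bool = True):
        self.epsilon = epsilon
        self.with_grf = with_grf

    def fit(self, X: WindowSet, y=None) -> "WindowNormalizer":
        if len(X) == 0:
            raise ValidationError("cannot fit a normalizer on zero windows")
        mask = X.valid_mask()
        flat = X.data[mask]                       # (n_valid_rows, 48)
        imu_mean = flat.mean(axis=0)
        imu_std = np.maximum(flat.std(axis=0), self.epsilon)
        grf_mean = grf_std = None
        if self.with_grf and X.grf is not None:
            gflat = X.grf[mask]
            grf_mean = gflat.mean(axis=0)
            grf_std = np.maximum(gflat.std(axis=0), self.epsilon)
        self.stats_ = NormalizationStats(
            imu_mean=imu_mean, imu_std=imu_std,
            grf_mean=grf_mean, grf_std=grf_std, epsilon=self.epsilon,
        ).validate()
        return self

    def transform(self, X: WindowSet) -> WindowSet:
        return apply_normalizer(X, self.stats_)

    def inverse_transform(self, X: WindowSet) -> WindowSet:
        return apply_normalizer(X, self.stats_, invert=True)


def fit_normalizer(train: WindowSet, epsilon: float = 1e-8) -> NormalizationStats:
    """Functional form of :class:`WindowNormalizer` fitting."""
    return WindowNormalizer(epsilon=epsilon).fit(train).stats_


def apply_normalizer(
    ws: WindowSet, stats: NormalizationStats, invert: bool = False
) -> WindowSet:
    """Z-score (or un-z-score) a window set; padded rows stay exactly zero."""
    mask = ws.valid_mask()[:, :, None]
    if invert:
        data = ws.data * stats.imu_std + stats.imu_mean
    else:
        data = (ws.data - stats.imu_mean) / stats.imu_std
    data = np.where(mask, data, 0.0)
    grf = None
    if ws.grf is not None:
        if stats.grf_mean is None:
            raise ValidationError("stats carry no GRF statistics for labeled windows")
        if invert:
            grf = ws.grf * stats.grf_std + stats.grf_mean
        else:
            grf = (ws.grf - stats.grf_mean) / stats.grf_std
        grf = np.where(mask, grf, 0.0)
    return WindowSet(
        data=data, grf=grf,
        participant_ids=ws.participant_ids, trial_ids=ws.trial_ids,
        starts=ws.starts, valid_lengths=ws.valid_lengths,
    )
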