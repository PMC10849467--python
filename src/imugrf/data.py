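"""In-memory containers: trials, windows, window sets, normalization stats.

All IMU matrices are ``(n_steps, 48)`` in the canonical column order defined
by :mod:`imugrf.layout`; GRF matrices are ``(n_steps, 3)`` in N/kg with
columns medial-lateral, anterior-posterior, vertical.  Windows are a fixed
128 samples; drop-landing trials shorter than that are zero-padded and carry
``valid_length`` so padded rows can be excluded from statistics and losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ValidationError
from .layout import N_AXES

WINDOW_LENGTH = 128
GRF_AXES = ("ml", "ap", "v")


@dataclass
class KinematicsTrial:
    """Per-time-step position (m) and orientation (unit quaternion, w-x-y-z
    order) of each instrumented segment."""

    participant_id: str
    sampling_rate: float
    positions: dict[str, np.ndarray]      # segment -> (n_steps, 3)
    orientations: dict[str, np.ndarray]   # segment -> (n_steps, 4)
    trial_id: str = ""

    @property
    def segments(self) -> list[str]:
        return list(self.positions)

    @property
    def n_steps(self) -> int:
        first = next(iter(self.positions.values()))
        return first.shape[0]

    def validate(self, *, quat_tol: float = 1e-6) -> "KinematicsTrial":
        n = self.n_steps
        if set(self.positions) != set(self.orientations):
            raise ValidationError("positions and orientations name different segments")
        for seg in self.positions:
            p, q = self.positions[seg], self.orientations[seg]
            if p.shape != (n, 3):
                raise ValidationError(f"segment {seg!r}: position shape {p.shape}")
            if q.shape != (n, 4):
                raise ValidationError(f"segment {seg!r}: orientation shape {q.shape}")
            norms = np.linalg.norm(q, axis=1)
            if not np.allclose(norms, 1.0, atol=quat_tol):
                raise ValidationError(
                    f"segment {seg!r}: non-unit quaternions "
                    f"(max deviation {np.abs(norms - 1).max():.2e})"
                )
        return self


@dataclass
class IMUTrial:
    """A continuous multi-sensor IMU recording, optionally with GRF labels
    and stance-onset annotations."""

    participant_id: str
    sampling_rate: float
    data: np.ndarray                      # (n_steps, 48)
    grf: np.ndarray | None = None         # (n_steps, 3), N/kg
    stance_onsets: np.ndarray | None = None
    trial_id: str = ""

    @property
    def n_steps(self) -> int:
        return self.data.shape[0]

    def validate(self) -> "IMUTrial":
        if self.data.ndim != 2 or self.data.shape[1] != N_AXES:
            raise ValidationError(
                f"IMU data must have {N_AXES} columns, got shape {self.data.shape}"
            )
        if self.grf is not None and self.grf.shape != (self.n_steps, 3):
            raise ValidationError(
                f"GRF shape {self.grf.shape} does not match n_steps={self.n_steps}"
            )
        if self.stance_onsets is not None and len(self.stance_onsets):
            onsets = np.asarray(self.stance_onsets)
            if np.any(np.diff(onsets) <= 0):
                raise ValidationError("stance_onsets must be strictly increasing")
            if onsets[0] < 0 or onsets[-1] >= self.n_steps:
                raise ValidationError("stance_onsets outside [0, n_steps)")
        return self


@dataclass
class IMUWindow:
    """A single 128-sample block of the 48-axis IMU matrix with provenance."""

    data: np.ndarray                  # (128, 48)
    participant_id: str
    trial_id: str = ""
    start: int = 0
    valid_length: int = WINDOW_LENGTH
    grf: np.ndarray | None = None     # (128, 3)

    def validate(self) -> "IMUWindow":
        if self.data.shape != (WINDOW_LENGTH, N_AXES):
            raise ValidationError(f"window data shape {self.data.shape}")
        if not 0 < self.valid_length <= WINDOW_LENGTH:
            raise ValidationError(f"valid_length {self.valid_length} out of range")
        if self.valid_length < WINDOW_LENGTH:
            if np.any(self.data[self.valid_length :] != 0):
                raise ValidationError("rows beyond valid_length must be zero")
            if self.grf is not None and np.any(self.grf[self.valid_length :] != 0):
                raise ValidationError("GRF rows beyond valid_length must be zero")
        if self.grf is not None and self.grf.shape != (WINDOW_LENGTH, 3):
            raise ValidationError(f"window GRF shape {self.grf.shape}")
        return self


class WindowSet:
    """Array-backed collection of :class:`IMUWindow` with homogeneous labels.

    Either every window carries GRF or none does; this keeps the on-disk
    store and batched training code simple.
    """

    def __init__(
        self,
        data: np.ndarray,
        participant_ids: np.ndarray,
        trial_ids: np.ndarray,
        starts: np.ndarray,
        valid_lengths: np.ndarray,
        grf: np.ndarray | None = None,
    ) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 3 or data.shape[1:] != (WINDOW_LENGTH, N_AXES):
            raise ValidationError(f"WindowSet data shape {data.shape}")
        n = data.shape[0]
        if grf is not None:
            grf = np.asarray(grf, dtype=float)
            if grf.shape != (n, WINDOW_LENGTH, 3):
                raise ValidationError(f"WindowSet grf shape {grf.shape}")
        self.data = data
        self.grf = grf
        self.participant_ids = np.asarray(participant_ids, dtype=object)
        self.trial_ids = np.asarray(trial_ids, dtype=object)
        self.starts = np.asarray(starts, dtype=int)
        self.valid_lengths = np.asarray(valid_lengths, dtype=int)
        for name in ("participant_ids", "trial_ids", "starts", "valid_lengths"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"metadata field {name} has wrong length")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_windows(cls, windows: list[IMUWindow]) -> "WindowSet":
        if not windows:
            raise ValidationError("cannot build a WindowSet from zero windows")
        has_grf = [w.grf is not None for w in windows]
        if any(has_grf) and not all(has_grf):
            raise ValidationError("windows mix labeled and unlabeled GRF")
        grf = np.stack([w.grf for w in windows]) if all(has_grf) else None
        return cls(
            data=np.stack([w.data for w in windows]),
            participant_ids=np.array([w.participant_id for w in windows], dtype=object),
            trial_ids=np.array([w.trial_id for w in windows], dtype=object),
            starts=np.array([w.start for w in windows], dtype=int),
            valid_lengths=np.array([w.valid_length for w in windows], dtype=int),
            grf=grf,
        )

    @classmethod
    def empty(cls, with_grf: bool = False) -> "WindowSet":
        return cls(
            data=np.empty((0, WINDOW_LENGTH, N_AXES)),
            participant_ids=np.empty(0, dtype=object),
            trial_ids=np.empty(0, dtype=object),
            starts=np.empty(0, dtype=int),
            valid_lengths=np.empty(0, dtype=int),
            grf=np.empty((0, WINDOW_LENGTH, 3)) if with_grf else None,
        )

    @classmethod
    def concatenate(cls, sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets]
        if not sets:
            raise ValidationError("nothing to concatenate")
        has_grf = [s.grf is not None for s in sets]
        if any(has_grf) and not all(has_grf):
            raise ValidationError("window sets mix labeled and unlabeled GRF")
        return cls(
            data=np.concatenate([s.data for s in sets]),
            participant_ids=np.concatenate([s.participant_ids for s in sets]),
            trial_ids=np.concatenate([s.trial_ids for s in sets]),
            starts=np.concatenate([s.starts for s in sets]),
            valid_lengths=np.concatenate([s.valid_lengths for s in sets]),
            grf=np.concatenate([s.grf for s in sets]) if all(has_grf) else None,
        )

    # -- protocol ----------------------------------------------------------
    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, idx) -> "WindowSet":
        """Subset by boolean mask, index array, or slice (always a WindowSet)."""
        if np.isscalar(idx) or isinstance(idx, (int, np.integer)):
            idx = [int(idx)]
        return WindowSet(
            data=self.data[idx],
            participant_ids=self.participant_ids[idx],
            trial_ids=self.trial_ids[idx],
            starts=self.starts[idx],
            valid_lengths=self.valid_lengths[idx],
            grf=self.grf[idx] if self.grf is not None else None,
        )

    def windows(self) -> Iterator[IMUWindow]:
        for i in range(len(self)):
            yield IMUWindow(
                data=self.data[i],
                participant_id=str(self.participant_ids[i]),
                trial_id=str(self.trial_ids[i]),
                start=int(self.starts[i]),
                valid_length=int(self.valid_lengths[i]),
                grf=None if self.grf is None else self.grf[i],
            )

    @property
    def has_grf(self) -> bool:
        return self.grf is not None

    def without_grf(self) -> "WindowSet":
        """The same windows with labels dropped (for SSL pre-training)."""
        return WindowSet(
            data=self.data, participant_ids=self.participant_ids,
            trial_ids=self.trial_ids, starts=self.starts,
            valid_lengths=self.valid_lengths,
        )

    def valid_mask(self) -> np.ndarray:
        """(n_windows, 128) boolean mask, True on rows within valid_length."""
        rows = np.arange(WINDOW_LENGTH)[None, :]
        return rows < self.valid_lengths[:, None]


@dataclass
class NormalizationStats:
    """Per-axis mean/std for the 48 IMU axes and, when fitted on labeled
    data, the 3 GRF axes.  Standard deviations are clamped at ``epsilon`` so
    z-scoring a constant axis stays finite (it maps to all zeros)."""

    imu_mean: np.ndarray
    imu_std: np.ndarray
    grf_mean: np.ndarray | None = None
    grf_std: np.ndarray | None = None
    epsilon: float = 1e-8

    def validate(self) -> "NormalizationStats":
        for std in (self.imu_std, self.grf_std):
            if std is not None and np.any(std < self.epsilon):
                raise ValidationError("stored std below epsilon clamp")
        return self
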