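"""Sensor layout: identities, attachments and mounting orientations of the 8 IMUs.

The canonical sensor order fixes the 48-column layout used everywhere in the
package: columns are sensor-major, and within each sensor the six channels are
``acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z`` (accelerometer in m/s², gyroscope
in deg/s).  The mounting convention follows the usual wearable placement:
sensor z along the segment surface normal, x pointing left during standing,
y completing the right-hand rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

CANONICAL_SENSORS: tuple[str, ...] = (
    "trunk",
    "pelvis",
    "l_thigh",
    "r_thigh",
    "l_shank",
    "r_shank",
    "l_foot",
    "r_foot",
)
N_SENSORS = 8
N_AXES = 48
AXIS_CONVENTION = "z-surface-normal/x-left/y-right-hand"

_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

ACC_COLUMNS = np.array(
    [s * 6 + c for s in range(N_SENSORS) for c in range(3)], dtype=int
)
GYR_COLUMNS = np.array(
    [s * 6 + 3 + c for s in range(N_SENSORS) for c in range(3)], dtype=int
)


def imu_column_names(sensors: tuple[str, ...] = CANONICAL_SENSORS) -> list[str]:
    """48 canonical column names, sensor-major, acc xyz then gyr xyz."""
    return [f"{ch}_{sensor}" for sensor in sensors for ch in _CHANNELS]


def sensor_columns(sensor: str) -> np.ndarray:
    """Indices of the 6 columns belonging to *sensor* in canonical order."""
    try:
        i = CANONICAL_SENSORS.index(sensor)
    except ValueError as exc:
        raise ValidationError(f"unknown sensor {sensor!r}") from exc
    return np.arange(i * 6, i * 6 + 6)


@dataclass(frozen=True)
class SensorLayout:
    """Identities, segment attachments, and mounting rotations of the 8 IMUs.

    ``mounting[s]`` rotates vectors from the segment frame into the sensor
    frame of sensor ``s`` (orthonormal, det +1).
    """

    sensor_names: tuple[str, ...] = CANONICAL_SENSORS
    segments: dict[str, str] = field(default_factory=dict)
    mounting: dict[str, np.ndarray] = field(default_factory=dict)
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        if not self.segments:
            object.__setattr__(
                self, "segments", {s: s for s in self.sensor_names}
            )
        if not self.mounting:
            object.__setattr__(
                self, "mounting", {s: np.eye(3) for s in self.sensor_names}
            )

    def mounting_matrix(self, sensor: str) -> np.ndarray:
        return np.asarray(self.mounting[sensor], dtype=float)


def validate_layout(layout: SensorLayout, *, tol: float = 1e-9) -> SensorLayout:
    """Check all layout invariants; return the layout unchanged if they hold.

    Raises
    ------
    ValidationError
        Wrong sensor count/order, or a mounting rotation that is not a proper
        rotation (orthonormal with determinant +1 within *tol*).
    """
    if tuple(layout.sensor_names) != CANONICAL_SENSORS:
        raise ValidationError(
            f"sensor_names must be the canonical 8-sensor order "
            f"{CANONICAL_SENSORS}, got {tuple(layout.sensor_names)}"
        )
    for sensor in layout.sensor_names:
        if sensor not in layout.mounting:
            raise ValidationError(f"missing mounting rotation for {sensor!r}")
        r = layout.mounting_matrix(sensor)
        if r.shape != (3, 3):
            raise ValidationError(
                f"mounting rotation for {sensor!r} has shape {r.shape}"
            )
        if not np.allclose(r @ r.T, np.eye(3), atol=tol):
            raise ValidationError(
                f"mounting rotation for {sensor!r} is not orthonormal"
            )
        if not np.isclose(np.linalg.det(r), 1.0, atol=tol):
            raise ValidationError(
                f"mounting rotation for {sensor!r} has determinant "
                f"{np.linalg.det(r):.6f}, expected +1"
            )
    return layout
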