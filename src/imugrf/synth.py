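"""Synthetic IMU generation from rigid-segment kinematics.

Accelerometer signals are obtained by twice-differentiating segment position,
adding gravity, and rotating the result into the sensor frame; gyroscope
signals come from the symmetric finite difference of orientation expressed in
the sensor frame.  Mounting perturbations (uniform per-axis rotations within
±10°) emulate placement variability when the same motion trial is reused
several times for pre-training.

All trials are expected at (or are brought to) 100 Hz after zero-lag
low-pass filtering at 15 Hz, the standard preprocessing for optical
motion-capture kinematics before differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .data import IMUTrial, KinematicsTrial
from .errors import LengthError, ValidationError
from .layout import N_AXES, SensorLayout

GRAVITY_MAGNITUDE = 9.81


@dataclass(frozen=True)
class GravityConvention:
    """Global gravity vector (m/s²) and its sign convention.

    The default is z-up with gravity ADDED to the kinematic acceleration, so
    a static, upright sensor reads +9.81 m/s² on its gravity-aligned axis —
    matching how a real accelerometer at rest measures specific force.
    """

    vector: tuple[float, float, float] = (0.0, 0.0, GRAVITY_MAGNITUDE)
    tag: str = "z-up/reaction-added"

    def __post_init__(self) -> None:
        mag = float(np.linalg.norm(self.vector))
        if abs(mag - GRAVITY_MAGNITUDE) > 1e-6:
            raise ValidationError(
                f"gravity magnitude {mag:.8f} differs from {GRAVITY_MAGNITUDE}"
            )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)


@dataclass(frozen=True)
class MountingPerturbation:
    """Per-sensor rotation angles (deg) about the sensor x, y, z axes."""

    angles_deg: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        for sensor, a in self.angles_deg.items():
            a = np.asarray(a, dtype=float)
            if a.shape != (3,):
                raise ValidationError(f"{sensor}: need 3 angles, got shape {a.shape}")
            if np.any(np.abs(a) > 10.0 + 1e-12):
                raise ValidationError(f"{sensor}: angle outside ±10 deg: {a}")

    def rotation(self, sensor: str) -> np.ndarray:
        """3×3 rotation composed intrinsically x→y→z about sensor axes."""
        a = np.asarray(self.angles_deg.get(sensor, np.zeros(3)), dtype=float)
        return Rotation.from_euler("XYZ", a, degrees=True).as_matrix()

    @classmethod
    def identity(cls, layout: SensorLayout) -> "MountingPerturbation":
        return cls({s: np.zeros(3) for s in layout.sensor_names})


def sample_perturbations(
    layout: SensorLayout,
    n_variants: int = 5,
    max_deg: float = 10.0,
    seed: int | None = None,
) -> list[MountingPerturbation]:
    """Draw *n_variants* mounting perturbations, each sensor angle uniform in
    [−max_deg, +max_deg]; reproducible for a fixed seed."""
    if n_variants < 1:
        raise ValidationError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_variants):
        angles = {
            s: rng.uniform(-max_deg, max_deg, size=3) for s in layout.sensor_names
        }
        out.append(MountingPerturbation(angles_deg=angles, seed=seed))
    return out


# ---------------------------------------------------------------------------
# filtering / resampling of kinematics
# ---------------------------------------------------------------------------

def _resample_columns(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Linear interpolation of each column onto a uniform fs_out grid covering
    the same duration (within one output sample)."""
    n_in = x.shape[0]
    duration = (n_in - 1) / fs_in
    n_out = int(np.floor(duration * fs_out)) + 1
    t_in = np.arange(n_in) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.column_stack([np.interp(t_out, t_in, x[:, j]) for j in range(x.shape[1])])


def lowpass_resample(
    trial: KinematicsTrial,
    cutoff: float = 15.0,
    order: int = 4,
    fs_out: float = 100.0,
) -> KinematicsTrial:
    """Zero-lag Butterworth low-pass filter of positions and orientations,
    then linear resampling to *fs_out*.

    Quaternion components are filtered and interpolated component-wise and
    re-normalized; for the smooth, well-sampled orientations this operates
    on, that is numerically indistinguishable from geodesic filtering.
    """
    fs_in = trial.sampling_rate
    if fs_in < 2 * cutoff:
        raise ValidationError(
            f"sampling rate {fs_in} Hz below Nyquist for cutoff {cutoff} Hz"
        )
    if trial.n_steps <= 3 * order:
        raise LengthError(
            f"trial has {trial.n_steps} steps; need > {3 * order} for stable filtering"
        )
    b, a = butter(order, cutoff / (fs_in / 2), btype="low")
    positions, orientations = {}, {}
    for seg in trial.segments:
        p = filtfilt(b, a, trial.positions[seg], axis=0)
        q = trial.orientations[seg]
        # enforce hemisphere continuity before component-wise filtering
        q = q.copy()
        flips = np.cumsum(np.sum(q[1:] * q[:-1], axis=1) < 0) % 2
        q[1:][flips == 1] *= -1
        q = filtfilt(b, a, q, axis=0)
        positions[seg] = _resample_columns(p, fs_in, fs_out)
        q = _resample_columns(q, fs_in, fs_out)
        orientations[seg] = q / np.linalg.norm(q, axis=1, keepdims=True)
    return KinematicsTrial(
        participant_id=trial.participant_id,
        sampling_rate=fs_out,
        positions=positions,
        orientations=orientations,
        trial_id=trial.trial_id,
    )


# ---------------------------------------------------------------------------
# IMU synthesis
# ---------------------------------------------------------------------------

def _angular_velocity_deg(rotations: Rotation, dt: float) -> np.ndarray:
    """Body-frame angular velocity (deg/s) by symmetric differencing.

    ω(t) is the rotation vector of R(t−1)⁻¹R(t+1) divided by 2Δt — a
    second-order accurate, frame-correct estimate; the endpoints use the
    one-sided neighbor pair.
    """
    n = len(rotations)
    lo = np.maximum(np.arange(n) - 1, 0)
    hi = np.minimum(np.arange(n) + 1, n - 1)
    rel = rotations[lo].inv() * rotations[hi]
    span = (hi - lo) * dt
    omega_rad = rel.as_rotvec() / span[:, None]
    return np.degrees(omega_rad)


def _second_derivative(p: np.ndarray, dt: float) -> np.ndarray:
    """Central second difference; endpoints copy the nearest interior value."""
    out = np.empty_like(p)
    out[1:-1] = (p[2:] - 2 * p[1:-1] + p[:-2]) / dt**2
    out[0] = out[1]
    out[-1] = out[-2]
    return out


def synthesize_imu(
    trial: KinematicsTrial,
    layout: SensorLayout,
    perturbation: MountingPerturbation | None = None,
    gravity: GravityConvention | None = None,
) -> IMUTrial:
    """Compute the 48-axis synthetic IMU trial for one kinematics trial.

    Per sensor the global-to-sensor orientation is
    ``R_sensor(t) = R_segment(t) · R_mount · R_perturb`` and

    * gyroscope  = body-frame angular velocity of ``R_sensor`` (deg/s),
    * accelerometer = ``R_sensorᵀ · (d²p/dt² + g)`` (m/s²).
    """
    if trial.n_steps < 3:
        raise LengthError("need at least 3 samples for a second derivative")
    if perturbation is None:
        perturbation = MountingPerturbation.identity(layout)
    if gravity is None:
        gravity = GravityConvention()
    dt = 1.0 / trial.sampling_rate
    n = trial.n_steps
    data = np.zeros((n, N_AXES))
    for i, sensor in enumerate(layout.sensor_names):
        seg = layout.segments[sensor]
        if seg not in trial.positions:
            raise ValidationError(f"trial lacks kinematics for segment {seg!r}")
        # scipy quats are (x, y, z, w); ours are (w, x, y, z)
        q_wxyz = trial.orientations[seg]
        r_seg = Rotation.from_quat(np.roll(q_wxyz, -1, axis=1))
        # segment->sensor map, perturbed in the sensor frame; sensor->global
        # is then R_seg · M'ᵀ
        m_pert = perturbation.rotation(sensor) @ layout.mounting_matrix(sensor)
        r_sensor = r_seg * Rotation.from_matrix(m_pert.T)

        gyro = _angular_velocity_deg(r_sensor, dt)
        a_global = _second_derivative(trial.positions[seg], dt) + gravity.array
        acc = r_sensor.inv().apply(a_global)

        data[:, i * 6 : i * 6 + 3] = acc
        data[:, i * 6 + 3 : i * 6 + 6] = gyro
    return IMUTrial(
        participant_id=trial.participant_id,
        sampling_rate=trial.sampling_rate,
        data=data,
        trial_id=trial.trial_id,
    )
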