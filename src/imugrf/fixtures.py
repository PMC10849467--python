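"""Synthetic multi-participant gait and drop-landing data with a known,
learnable IMU↔GRF relationship.

The generator emulates the *structure* of motion-capture/IMU/force-plate
datasets — an 8-segment rigid chain with periodic, participant-specific
sagittal joint trajectories (band-limited harmonic mixtures of the stride
frequency, ≤ 6 Hz), stance-phase right-leg GRF with the classic double-peak
vertical profile, drop-landing impulses, and optional stillness segments at
trial boundaries to exercise the exclusion filters.  GRF and IMU are both
deterministic smooth functions of the same gait phase, so the estimation
task is learnable by construction; biomechanical fidelity is a non-goal.

Everything is seeded: regenerating with the same config reproduces both
kinematics and GRF bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .data import IMUTrial, KinematicsTrial, WindowSet
from .errors import ValidationError
from .layout import ACC_COLUMNS, GYR_COLUMNS, SensorLayout
from .preprocessing import (
    WindowingConfig,
    extract_gait_windows,
    filter_outliers,
    filter_still,
    pad_trial_to_window,
    segment_windows,
)
from .synth import lowpass_resample, sample_perturbations, synthesize_imu

BODY_WEIGHT_NKG = 9.81


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the generator.

    Defaults model relaxed overground walking: cadence 100–130 steps/min,
    double-peak vertical GRF peaking near 1.2 body weight, IMU noise at the
    level of modern MEMS sensors (0.05 m/s² accel, 0.2 deg/s gyro).
    """

    n_participants: int = 6
    duration_s: float = 60.0
    trials_per_participant: int = 1
    cadence_range: tuple[float, float] = (100.0, 130.0)  # steps/min
    gain_variation: float = 0.15        # relative participant-to-participant spread
    phase_variation: float = 1.0        # rad, random phase offsets
    noise_std_acc: float = 0.05         # m/s²
    noise_std_gyro: float = 0.2         # deg/s
    stillness_fraction: float = 0.0     # fraction of trial frozen at boundaries
    sampling_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("fixture seed is mandatory")
        if self.cadence_range[0] > self.cadence_range[1]:
            raise ValidationError("cadence_range must be (low, high)")


# ---------------------------------------------------------------------------
# participant parameters (deterministic per config + participant id)
# ---------------------------------------------------------------------------

def participant_id(i: int) -> str:
    return f"P{i:02d}"


def _participant_rng(cfg: FixtureConfig, pid: str) -> np.random.Generator:
    idx = int(pid.lstrip("P"))
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, idx]))


def _participant_params(cfg: FixtureConfig, pid: str) -> dict:
    rng = _participant_rng(cfg, pid)
    g = cfg.gain_variation
    cadence = rng.uniform(*cfg.cadence_range)
    return {
        "stride_hz": cadence / 60.0 / 2.0,      # two steps per stride
        "phase0": rng.uniform(0, cfg.phase_variation),
        # sagittal amplitudes (rad): fundamental dominates; harmonics <= 4f
        "a_thigh": np.deg2rad(25.0) * (1 + g * rng.standard_normal()),
        "a_shank": np.deg2rad(35.0) * (1 + g * rng.standard_normal()),
        "a_foot": np.deg2rad(15.0) * (1 + g * rng.standard_normal()),
        "h2": 0.3 * (1 + g * rng.standard_normal()),
        "h3": 0.1 * (1 + g * rng.standard_normal()),
        "peak_vgrf": 1.2 * BODY_WEIGHT_NKG * (1 + 0.5 * g * rng.standard_normal()),
        "landing_omega": rng.uniform(35.0, 45.0),   # rad/s, impact oscillation
        "landing_zeta": rng.uniform(0.25, 0.35),
    }


# ---------------------------------------------------------------------------
# gait kinematics
# ---------------------------------------------------------------------------

_SEGMENT_LENGTHS = {"thigh": 0.42, "shank": 0.42}
_HIP_OFFSET = 0.10      # lateral, m
_STANCE_FRACTION = 0.6  # of the stride cycle


def _gait_angles(t: np.ndarray, p: dict, side: str) -> dict[str, np.ndarray]:
    """Sagittal (about the lateral x-axis) segment angles, rad."""
    shift = 0.0 if side == "r" else np.pi
    ph = 2 * np.pi * p["stride_hz"] * t + p["phase0"] + shift
    thigh = p["a_thigh"] * (np.sin(ph) + p["h2"] * 0.3 * np.sin(2 * ph))
    shank = p["a_shank"] * (
        0.6 * np.sin(ph - 0.6) + p["h2"] * np.sin(2 * ph - 0.4)
        + p["h3"] * np.sin(3 * ph)
    )
    foot = p["a_foot"] * (
        0.5 * np.sin(ph - 1.0) + p["h2"] * 0.6 * np.sin(2 * ph - 0.9)
        + p["h3"] * np.sin(4 * ph)
    )
    return {"thigh": thigh, "shank": shank, "foot": foot}


def _quat_about_x(theta: np.ndarray) -> np.ndarray:
    """Unit quaternions (w, x, y, z) for rotations about the global x-axis."""
    q = np.zeros((len(theta), 4))
    q[:, 0] = np.cos(theta / 2)
    q[:, 1] = np.sin(theta / 2)
    return q


def _effective_time(t: np.ndarray, cfg: FixtureConfig) -> np.ndarray:
    """Clamp time to freeze the first/last stillness segments (half each)."""
    if cfg.stillness_fraction <= 0:
        return t
    still = cfg.stillness_fraction * cfg.duration_s / 2
    return np.clip(t, still, cfg.duration_s - still)


def generate_gait_kinematics(cfg: FixtureConfig) -> list[KinematicsTrial]:
    """Periodic 8-segment gait kinematics, one or more trials per participant.

    Trials are deterministic per seed; with ``stillness_fraction`` > 0 the
    boundary segments are frozen (constant pose) to exercise the stillness
    filter downstream.
    """
    trials = []
    n = int(round(cfg.duration_s * cfg.sampling_rate))
    for i in range(cfg.n_participants):
        pid = participant_id(i)
        p = _participant_params(cfg, pid)
        for k in range(cfg.trials_per_participant):
            t_grid = np.arange(n) / cfg.sampling_rate
            t = _effective_time(t_grid, cfg) + k * 977.0  # trial-specific offset
            positions: dict[str, np.ndarray] = {}
            orientations: dict[str, np.ndarray] = {}

            ph = 2 * np.pi * p["stride_hz"] * t + p["phase0"]
            pelvis = np.column_stack([
                0.04 * np.sin(ph),
                0.05 * np.sin(ph + 0.3),
                1.00 + 0.03 * np.sin(2 * ph),
            ])
            positions["pelvis"] = pelvis
            orientations["pelvis"] = _quat_about_x(0.05 * np.sin(2 * ph))
            positions["trunk"] = pelvis + np.array([0.0, 0.0, 0.30])
            orientations["trunk"] = _quat_about_x(0.06 * np.sin(ph + 0.5))

            for side, sign in (("r", -1.0), ("l", 1.0)):
                ang = _gait_angles(t, p, side)
                hip = pelvis + np.array([sign * _HIP_OFFSET, 0.0, -0.05])
                r_th = Rotation.from_euler("x", ang["thigh"][:, None])
                knee = hip + r_th.apply(np.array([0.0, 0.0, -_SEGMENT_LENGTHS["thigh"]]))
                r_sh = Rotation.from_euler("x", ang["shank"][:, None])
                ankle = knee + r_sh.apply(np.array([0.0, 0.0, -_SEGMENT_LENGTHS["shank"]]))
                prefix = f"{side}_"
                positions[prefix + "thigh"] = (hip + knee) / 2
                orientations[prefix + "thigh"] = _quat_about_x(ang["thigh"])
                positions[prefix + "shank"] = (knee + ankle) / 2
                orientations[prefix + "shank"] = _quat_about_x(ang["shank"])
                r_ft = Rotation.from_euler("x", ang["foot"][:, None])
                positions[prefix + "foot"] = ankle + r_ft.apply(
                    np.array([0.0, 0.08, -0.05])
                )
                orientations[prefix + "foot"] = _quat_about_x(ang["foot"])

            trials.append(
                KinematicsTrial(
                    participant_id=pid,
                    sampling_rate=cfg.sampling_rate,
                    positions=positions,
                    orientations=orientations,
                    trial_id=f"{pid}_gait{k}",
                ).validate()
            )
    return trials


# ---------------------------------------------------------------------------
# GRF
# ---------------------------------------------------------------------------

def _vgrf_shape(s: np.ndarray) -> np.ndarray:
    """Double-peak stance profile on s ∈ [0, 1), zero at the ends,
    normalized to unit maximum."""
    m = np.sin(np.pi * s) + 0.35 * np.sin(3 * np.pi * s)
    return np.clip(m, 0.0, None) / 1.0521  # max of the raw shape

def generate_grf(trial: KinematicsTrial, cfg: FixtureConfig
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Right-leg GRF (n_steps × 3, N/kg) and stance-onset sample indices for
    a gait kinematics trial; recomputed deterministically from the trial's
    participant parameters and time grid."""
    p = _participant_params(cfg, trial.participant_id)
    n = trial.n_steps
    k = int(trial.trial_id.rsplit("gait", 1)[-1]) if "gait" in trial.trial_id else 0
    t_grid = np.arange(n) / trial.sampling_rate
    t = _effective_time(t_grid, cfg) + k * 977.0
    cycle = (p["stride_hz"] * t + p["phase0"] / (2 * np.pi)) % 1.0
    in_stance = cycle < _STANCE_FRACTION
    s = np.where(in_stance, cycle / _STANCE_FRACTION, 0.0)
    v = np.where(in_stance, p["peak_vgrf"] * _vgrf_shape(s), 0.0)
    ml = np.where(in_stance, 0.08 * p["peak_vgrf"] * np.sin(np.pi * s), 0.0)
    ap = np.where(in_stance, -0.22 * p["peak_vgrf"] * np.sin(2 * np.pi * s), 0.0)
    grf = np.column_stack([ml, ap, v])
    onsets = np.flatnonzero(in_stance[1:] & ~in_stance[:-1]) + 1
    return grf, onsets


# ---------------------------------------------------------------------------
# drop landing
# ---------------------------------------------------------------------------

def generate_drop_landing_trials(
    cfg: FixtureConfig, n_trials_per_participant: int = 5,
    n_steps: int = 80, drop_height: float = 0.30,
) -> list[tuple[KinematicsTrial, np.ndarray, np.ndarray]]:
    """Short (0.8 s, 80-step) drop-landing trials: free fall from a 30 cm
    box, impact, damped settling.  Returns (kinematics, grf, onsets) per
    trial; vGRF is derived from pelvis acceleration so it is exactly zero in
    flight and exactly consistent with the synthetic IMU signals."""
    out = []
    g = BODY_WEIGHT_NKG
    for i in range(cfg.n_participants):
        pid = participant_id(i)
        p = _participant_params(cfg, pid)
        rng = _participant_rng(cfg, pid)
        for k in range(n_trials_per_participant):
            dt = 1.0 / cfg.sampling_rate
            t = np.arange(n_steps) * dt
            h = drop_height * (1 + 0.05 * rng.standard_normal())
            t_impact = np.sqrt(2 * h / g)
            omega = p["landing_omega"] * (1 + 0.05 * rng.standard_normal())
            zeta = p["landing_zeta"]
            wd = omega * np.sqrt(1 - zeta**2)
            v_i = -g * t_impact
            tau = t - t_impact
            z_fall = 1.0 + h - 0.5 * g * t**2
            z_land = 1.0 + (v_i / wd) * np.exp(-zeta * omega * tau) * np.sin(wd * tau)
            z = np.where(t < t_impact, z_fall, z_land)
            pelvis = np.column_stack([np.zeros(n_steps), np.zeros(n_steps), z])

            # exact second derivative of the closed-form trajectory
            a_fall = np.full(n_steps, -g)
            expo = np.exp(-zeta * omega * tau)
            a_land = (v_i / wd) * expo * (
                (zeta**2 * omega**2 - wd**2) * np.sin(wd * tau)
                - 2 * zeta * omega * wd * np.cos(wd * tau)
            )
            a_z = np.where(t < t_impact, a_fall, a_land)
            vgrf = np.clip(0.55 * (a_z + g), 0.0, None)
            ml = 0.04 * vgrf * np.sin(3.0 * np.maximum(tau, 0))
            ap = -0.08 * vgrf * np.sin(5.0 * np.maximum(tau, 0))
            grf = np.column_stack([ml, ap, vgrf])
            onsets = np.array([int(np.searchsorted(t, t_impact))])

            flex = np.where(tau > 0, 0.6 * (1 - np.exp(-omega * np.maximum(tau, 0))), 0.0)
            positions: dict[str, np.ndarray] = {}
            orientations: dict[str, np.ndarray] = {}
            positions["pelvis"] = pelvis
            orientations["pelvis"] = _quat_about_x(0.1 * flex)
            positions["trunk"] = pelvis + np.array([0.0, 0.0, 0.30])
            orientations["trunk"] = _quat_about_x(0.3 * flex)
            for side, sign in (("r", -1.0), ("l", 1.0)):
                hip = pelvis + np.array([sign * _HIP_OFFSET, 0.0, -0.05])
                th = 0.8 * flex
                sh = -0.9 * flex
                r_th = Rotation.from_euler("x", th[:, None])
                knee = hip + r_th.apply(np.array([0.0, 0.0, -_SEGMENT_LENGTHS["thigh"]]))
                r_sh = Rotation.from_euler("x", sh[:, None])
                ankle = knee + r_sh.apply(np.array([0.0, 0.0, -_SEGMENT_LENGTHS["shank"]]))
                positions[f"{side}_thigh"] = (hip + knee) / 2
                orientations[f"{side}_thigh"] = _quat_about_x(th)
                positions[f"{side}_shank"] = (knee + ankle) / 2
                orientations[f"{side}_shank"] = _quat_about_x(sh)
                positions[f"{side}_foot"] = ankle + np.array([0.0, 0.08, -0.05])
                orientations[f"{side}_foot"] = _quat_about_x(0.2 * flex)

            kin = KinematicsTrial(
                participant_id=pid, sampling_rate=cfg.sampling_rate,
                positions=positions, orientations=orientations,
                trial_id=f"{pid}_drop{k}",
            ).validate()
            out.append((kin, grf, onsets))
    return out


# ---------------------------------------------------------------------------
# end-to-end corpus assembly
# ---------------------------------------------------------------------------

def _add_imu_noise(trial: IMUTrial, cfg: FixtureConfig,
                   rng: np.random.Generator) -> IMUTrial:
    data = trial.data.copy()
    data[:, ACC_COLUMNS] += rng.normal(0, cfg.noise_std_acc,
                                       size=data[:, ACC_COLUMNS].shape)
    data[:, GYR_COLUMNS] += rng.normal(0, cfg.noise_std_gyro,
                                       size=data[:, GYR_COLUMNS].shape)
    return replace(trial, data=data)


def make_labeled_trial(kin: KinematicsTrial, cfg: FixtureConfig,
                       layout: SensorLayout | None = None,
                       rng: np.random.Generator | None = None) -> IMUTrial:
    """Synthesize the IMU trial for gait kinematics and attach GRF labels
    and stance onsets (noise seeded from the config unless *rng* given)."""
    layout = layout or SensorLayout()
    if rng is None:
        rng = _participant_rng(cfg, kin.participant_id)
    imu = synthesize_imu(kin, layout)
    imu = _add_imu_noise(imu, cfg, rng)
    grf, onsets = generate_grf(kin, cfg)
    return replace(imu, grf=grf, stance_onsets=onsets)


def make_corpus(
    cfg: FixtureConfig,
    labeled_fraction: float = 1.0,
    n_orientation_variants: int = 1,
    layout: SensorLayout | None = None,
) -> tuple[WindowSet, WindowSet]:
    """Run the full generation pipeline end-to-end.

    Returns ``(pretrain, labeled)``: an unlabeled pre-training WindowSet
    (low-pass filtered kinematics → synthetic IMU under random mounting
    perturbations → windowing → stillness/outlier filters) and a labeled
    downstream WindowSet (gait windows starting 40 samples before each
    stance onset, with GRF).  Counts removed by each filter are logged.
    """
    layout = layout or SensorLayout()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_007]))
    kin_trials = generate_gait_kinematics(cfg)
    wcfg = WindowingConfig()

    pretrain_sets = []
    for kin in kin_trials:
        filtered = lowpass_resample(kin, fs_out=cfg.sampling_rate)
        perturbations = sample_perturbations(
            layout, n_variants=n_orientation_variants,
            seed=int(rng.integers(2**31)),
        )
        for pert in perturbations:
            imu = synthesize_imu(filtered, layout, pert)
            imu = _add_imu_noise(imu, cfg, rng)
            ws = segment_windows(imu, wcfg)
            if len(ws):
                ws = filter_still(ws, wcfg.stillness_threshold)
            if len(ws):
                ws = filter_outliers(ws, wcfg.acc_max, wcfg.gyro_max)
            if len(ws):
                pretrain_sets.append(ws)
    pretrain = WindowSet.concatenate(pretrain_sets)

    labeled_sets = []
    for kin in kin_trials:
        trial = make_labeled_trial(kin, cfg, layout, rng)
        ws = extract_gait_windows(trial, wcfg)
        if len(ws):
            labeled_sets.append(ws)
    labeled = WindowSet.concatenate(labeled_sets)
    if labeled_fraction < 1.0:
        k = max(1, int(round(labeled_fraction * len(labeled))))
        idx = np.sort(rng.permutation(len(labeled))[:k])
        labeled = labeled[idx]
    return pretrain, labeled


def make_drop_landing_windows(cfg: FixtureConfig,
                              n_trials_per_participant: int = 5,
                              layout: SensorLayout | None = None) -> WindowSet:
    """Zero-padded 80-step drop-landing windows with GRF labels."""
    layout = layout or SensorLayout()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 20_011]))
    windows = []
    for kin, grf, onsets in generate_drop_landing_trials(
        cfg, n_trials_per_participant
    ):
        imu = synthesize_imu(kin, layout)
        imu = _add_imu_noise(imu, cfg, rng)
        trial = replace(imu, grf=grf, stance_onsets=onsets)
        windows.append(pad_trial_to_window(trial))
    return WindowSet.from_windows(windows)
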