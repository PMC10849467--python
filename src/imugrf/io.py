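"""File I/O: trial CSVs with YAML sidecars, and the HDF5 window store.

Trial CSV schema
----------------
Header row; columns ``time_s``, then the 48 IMU columns named
``<acc|gyr>_<x|y|z>_<sensor>`` in canonical sensor-major order, then
optionally ``grf_ml, grf_ap, grf_v`` (N/kg) and ``stance_onset`` (0/1
marker).  A sidecar YAML (``<stem>.yaml`` next to the CSV, falling back to
``meta.yaml`` in the same directory) holds ``participant_id``,
``sampling_rate`` and optionally ``body_mass_kg``.

Kinematics CSV schema
---------------------
``time_s``, then per segment ``pos_<x|y|z>_<segment>`` (m) and
``quat_<w|x|y|z>_<segment>`` (unit quaternion); same sidecar convention.

Window store
------------
A single HDF5 file with datasets ``data`` (n, 128, 48), optional ``grf``
(n, 128, 3), and per-window metadata arrays; round trips are bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import WINDOW_LENGTH, IMUTrial, KinematicsTrial, WindowSet
from .errors import FormatError, IntegrityError, SchemaError, ValidationError
from .layout import N_AXES, imu_column_names

_GRF_COLUMNS = ("grf_ml", "grf_ap", "grf_v")
_STORE_VERSION = "imugrf-window-store-1"


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def read_sidecar(csv_path: Path) -> dict:
    csv_path = Path(csv_path)
    for candidate in (csv_path.with_suffix(".yaml"), csv_path.parent / "meta.yaml"):
        if candidate.exists():
            with open(candidate) as fh:
                meta = yaml.safe_load(fh) or {}
            if not isinstance(meta, dict):
                raise FormatError(f"sidecar {candidate} is not a mapping")
            return meta
    return {}


def write_sidecar(path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _require_meta(meta: dict, key: str, default=None):
    if key in meta:
        return meta[key]
    if default is not None:
        return default
    raise SchemaError(f"sidecar is missing required field {key!r}")


# ---------------------------------------------------------------------------
# IMU trial CSV
# ---------------------------------------------------------------------------

def _check_time(df: pd.DataFrame, path: Path) -> np.ndarray:
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: non-monotone timestamps in 'time_s'")
    return t


def read_imu_trial(path: str | Path, sidecar: dict | None = None) -> IMUTrial:
    """Read a trial CSV into an :class:`IMUTrial` in canonical column order.

    Raises :class:`SchemaError` naming any missing or unexpected column and
    :class:`FormatError` on non-monotone timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path)
    t = _check_time(df, path)

    expected = imu_column_names()
    for col in expected:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing IMU column {col!r}")
    known = {"time_s", *expected, *_GRF_COLUMNS, "stance_onset"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")

    data = df[expected].to_numpy(dtype=float)
    assert data.shape[1] == N_AXES

    grf = None
    present_grf = [c for c in _GRF_COLUMNS if c in df.columns]
    if present_grf:
        if len(present_grf) != 3:
            missing = sorted(set(_GRF_COLUMNS) - set(present_grf))
            raise SchemaError(f"{path}: incomplete GRF columns, missing {missing}")
        grf = df[list(_GRF_COLUMNS)].to_numpy(dtype=float)

    stance_onsets = None
    if "stance_onset" in df.columns:
        marks = df["stance_onset"].to_numpy()
        stance_onsets = np.flatnonzero(marks != 0)

    meta = sidecar if sidecar is not None else read_sidecar(path)
    if "sampling_rate" in meta:
        fs = float(meta["sampling_rate"])
    elif len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        raise SchemaError(f"{path}: sampling_rate not in sidecar and not inferable")
    participant_id = str(meta.get("participant_id", path.stem))

    return IMUTrial(
        participant_id=participant_id,
        sampling_rate=fs,
        data=data,
        grf=grf,
        stance_onsets=stance_onsets,
        trial_id=path.stem,
    ).validate()


def write_imu_trial(trial: IMUTrial, path: str | Path, write_meta: bool = True) -> None:
    """Write an :class:`IMUTrial` to the documented CSV schema."""
    path = Path(path)
    trial.validate()
    t = np.arange(trial.n_steps) / trial.sampling_rate
    df = pd.DataFrame({"time_s": t})
    df[imu_column_names()] = trial.data
    if trial.grf is not None:
        df[list(_GRF_COLUMNS)] = trial.grf
    if trial.stance_onsets is not None:
        marks = np.zeros(trial.n_steps, dtype=int)
        marks[np.asarray(trial.stance_onsets, dtype=int)] = 1
        df["stance_onset"] = marks
    df.to_csv(path, index=False)
    if write_meta:
        write_sidecar(
            path.with_suffix(".yaml"),
            {"participant_id": trial.participant_id,
             "sampling_rate": float(trial.sampling_rate)},
        )


# ---------------------------------------------------------------------------
# kinematics CSV
# ---------------------------------------------------------------------------

def read_kinematics_trial(path: str | Path, sidecar: dict | None = None) -> KinematicsTrial:
    path = Path(path)
    df = pd.read_csv(path)
    _check_time(df, path)
    segments: list[str] = []
    for col in df.columns:
        if col.startswith("pos_x_"):
            segments.append(col[len("pos_x_"):])
    if not segments:
        raise SchemaError(f"{path}: no 'pos_x_<segment>' columns found")
    positions, orientations = {}, {}
    for seg in segments:
        pcols = [f"pos_{ax}_{seg}" for ax in "xyz"]
        qcols = [f"quat_{ax}_{seg}" for ax in "wxyz"]
        for c in pcols + qcols:
            if c not in df.columns:
                raise SchemaError(f"{path}: missing column {c!r}")
        positions[seg] = df[pcols].to_numpy(dtype=float)
        orientations[seg] = df[qcols].to_numpy(dtype=float)
    meta = sidecar if sidecar is not None else read_sidecar(path)
    return KinematicsTrial(
        participant_id=str(meta.get("participant_id", path.stem)),
        sampling_rate=float(_require_meta(meta, "sampling_rate")),
        positions=positions,
        orientations=orientations,
        trial_id=path.stem,
    ).validate()


def write_kinematics_trial(trial: KinematicsTrial, path: str | Path,
                           write_meta: bool = True) -> None:
    path = Path(path)
    trial.validate()
    t = np.arange(trial.n_steps) / trial.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for seg in trial.segments:
        for i, ax in enumerate("xyz"):
            df[f"pos_{ax}_{seg}"] = trial.positions[seg][:, i]
        for i, ax in enumerate("wxyz"):
            df[f"quat_{ax}_{seg}"] = trial.orientations[seg][:, i]
    df.to_csv(path, index=False)
    if write_meta:
        write_sidecar(
            path.with_suffix(".yaml"),
            {"participant_id": trial.participant_id,
             "sampling_rate": float(trial.sampling_rate)},
        )


# ---------------------------------------------------------------------------
# window store (HDF5)
# ---------------------------------------------------------------------------

def write_window_store(windows: WindowSet, path: str | Path) -> None:
    """Persist a non-empty :class:`WindowSet`; round trip is bit-exact."""
    if len(windows) == 0:
        raise ValidationError("refusing to write an empty WindowSet")
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _STORE_VERSION
        f.create_dataset("data", data=windows.data.astype(np.float64))
        if windows.grf is not None:
            f.create_dataset("grf", data=windows.grf.astype(np.float64))
        f.create_dataset("participant_ids",
                         data=[str(x) for x in windows.participant_ids],
                         dtype=str_dt)
        f.create_dataset("trial_ids",
                         data=[str(x) for x in windows.trial_ids], dtype=str_dt)
        f.create_dataset("starts", data=windows.starts)
        f.create_dataset("valid_lengths", data=windows.valid_lengths)


def read_window_store(path: str | Path) -> WindowSet:
    """Read a window store written by :func:`write_window_store`.

    Raises :class:`IntegrityError` if the file is corrupt or inconsistent.
    """
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != _STORE_VERSION:
                raise IntegrityError(
                    f"{path}: unknown window-store format "
                    f"{f.attrs.get('format_version')!r}"
                )
            data = f["data"][...]
            grf = f["grf"][...] if "grf" in f else None
            pids = np.array([s.decode() if isinstance(s, bytes) else str(s)
                             for s in f["participant_ids"][...]], dtype=object)
            tids = np.array([s.decode() if isinstance(s, bytes) else str(s)
                             for s in f["trial_ids"][...]], dtype=object)
            starts = f["starts"][...]
            valid = f["valid_lengths"][...]
    except (OSError, KeyError) as exc:
        raise IntegrityError(f"{path}: corrupt window store ({exc})") from exc
    if data.ndim != 3 or data.shape[1:] != (WINDOW_LENGTH, N_AXES):
        raise IntegrityError(f"{path}: data dataset has shape {data.shape}")
    try:
        return WindowSet(data=data, grf=grf, participant_ids=pids,
                         trial_ids=tids, starts=starts, valid_lengths=valid)
    except ValidationError as exc:
        raise IntegrityError(f"{path}: inconsistent store ({exc})") from exc
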