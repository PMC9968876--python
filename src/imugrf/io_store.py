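"""On-disk formats and the in-memory session data model.

CSV dialect: comma separated, dot decimal, single header row, UTF-8,
time in seconds as float.  Accelerations are stored in m/s^2, angular
velocities in rad/s, forces in newtons.  The manifest is a YAML
document, one per participant cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, DataError, FormatError

GRAVITY = 9.81  # m/s^2, body-weight conversion

IMU_SITES = ("left_foot", "right_foot", "sacrum")
IMU_COLUMNS = ["time_s", "ax_ms2", "ay_ms2", "az_ms2", "gx_rads", "gy_rads", "gz_rads"]
FORCE_COLUMNS = ["time_s", "force_left_n", "force_right_n"]

#: filename suffix per mounting site, ``<trial>_{lfoot|rfoot|sacrum}.csv``
SITE_SUFFIX = {"left_foot": "lfoot", "right_foot": "rfoot", "sacrum": "sacrum"}


@dataclass
class ImuRecording:
    """One sensor's 6-channel inertial stream.

    Attributes
    ----------
    site : str
        Mounting site, one of ``left_foot``, ``right_foot``, ``sacrum``.
    time : ndarray
        Seconds from session start, strictly increasing.
    accel : ndarray, shape (n, 3)
        Linear acceleration, m/s^2.
    gyro : ndarray, shape (n, 3)
        Angular velocity, rad/s.
    rate : float
        Nominal sample rate in Hz (200 for the supported hardware).
    """

    site: str
    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if self.site not in IMU_SITES:
            raise DataError(f"unknown IMU site {self.site!r}")
        if self.rate <= 0:
            raise DataError("sample rate must be positive")
        if self.accel.shape[1] != 3 or self.gyro.shape[1] != 3:
            raise DataError("IMU stream must carry exactly 6 data channels")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise DataError("IMU timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.accel)):
            raise DataError("non-finite acceleration values")


@dataclass
class ForceRecording:
    """Bilateral insole normal forces plus the body weight used for BW scaling."""

    time: np.ndarray
    force_left: np.ndarray
    force_right: np.ndarray
    rate: float
    body_weight: float

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise DataError("body weight must be positive")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise DataError("force timestamps must be strictly increasing")


@dataclass
class TrialSpec:
    """One trial entry of a manifest."""

    trial_id: str
    pace_label: str
    target_velocity: float
    imu_paths: dict  # site -> path
    force_path: str

    def __post_init__(self) -> None:
        if set(self.imu_paths) != set(IMU_SITES):
            raise DataError(
                f"trial {self.trial_id}: need IMU paths for exactly {IMU_SITES}"
            )


@dataclass
class TrialManifest:
    """Per-participant description of recorded trials."""

    participant_id: str
    mass_kg: float
    trials: list = field(default_factory=list)
    seed: int | None = None

    @property
    def body_weight(self) -> float:
        return self.mass_kg * GRAVITY


def _infer_rate(time: np.ndarray) -> float:
    if len(time) < 2:
        raise DataError("need at least two samples to infer a sample rate")
    dt = float(np.median(np.diff(time)))
    if dt <= 0:
        raise DataError("non-monotone timestamps")
    return 1.0 / dt


def site_from_filename(path: str | Path) -> str:
    stem = Path(path).stem
    for site, suffix in SITE_SUFFIX.items():
        if stem.endswith("_" + suffix):
            return site
    raise FormatError(f"cannot infer IMU site from filename {path!r}")


def read_imu_csv(path: str | Path, site: str | None = None) -> ImuRecording:
    """Read one IMU CSV (see :data:`IMU_COLUMNS` for the dialect)."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != IMU_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {IMU_COLUMNS}, found {list(df.columns)}"
        )
    time = df["time_s"].to_numpy(float)
    if len(time) > 1 and not np.all(np.diff(time) > 0):
        raise DataError(f"{path}: time column not strictly increasing")
    if site is None:
        site = site_from_filename(path)
    rate = _infer_rate(time)
    return ImuRecording(
        site=site,
        time=time,
        accel=df[["ax_ms2", "ay_ms2", "az_ms2"]].to_numpy(float),
        gyro=df[["gx_rads", "gy_rads", "gz_rads"]].to_numpy(float),
        rate=rate,
    )


def write_imu_csv(rec: ImuRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.accel, rec.gyro]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_force_csv(path: str | Path, mass_kg: float) -> ForceRecording:
    """Read an insole CSV; clamps small negative readings, rejects large ones."""
    if mass_kg <= 0:
        raise ContractError("mass_kg must be positive")
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != FORCE_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {FORCE_COLUMNS}, found {list(df.columns)}"
        )
    time = df["time_s"].to_numpy(float)
    left = df["force_left_n"].to_numpy(float)
    right = df["force_right_n"].to_numpy(float)
    if np.any(left < -1.0) or np.any(right < -1.0):
        raise DataError(f"{path}: force below -1 N, sensor fault suspected")
    left = np.clip(left, 0.0, None)
    right = np.clip(right, 0.0, None)
    return ForceRecording(
        time=time,
        force_left=left,
        force_right=right,
        rate=_infer_rate(time),
        body_weight=mass_kg * GRAVITY,
    )


def write_force_csv(rec: ForceRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "force_left_n": rec.force_left,
            "force_right_n": rec.force_right,
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def write_estimates_csv(
    trial_id: str,
    time: Sequence[float],
    measured_bw: Sequence[float],
    estimated_bw: Sequence[float],
    path: str | Path,
) -> None:
    """Write per-sample measured/estimated GRF (BW) for one trial."""
    time = np.asarray(time, float)
    measured_bw = np.asarray(measured_bw, float)
    estimated_bw = np.asarray(estimated_bw, float)
    if not (len(time) == len(measured_bw) == len(estimated_bw)):
        raise ContractError("time/measured/estimated must have equal lengths")
    df = pd.DataFrame(
        {
            "time_s": time,
            "grf_bw_measured": measured_bw,
            "grf_bw_estimated": estimated_bw,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_estimates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["time_s", "grf_bw_measured", "grf_bw_estimated"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    return df


def read_manifest(path: str | Path) -> TrialManifest:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "participant_id" not in doc:
        raise FormatError(f"{path}: not a trial manifest")
    mass = float(doc["mass_kg"])
    if not math.isfinite(mass) or mass <= 0:
        raise DataError(f"{path}: bad mass_kg {mass}")
    trials = []
    for t in doc.get("trials", []):
        v = float(t["target_velocity"])
        trials.append(
            TrialSpec(
                trial_id=str(t["trial_id"]),
                pace_label=str(t.get("pace_label", "")),
                target_velocity=v,
                imu_paths={k: str(p) for k, p in t["imu_paths"].items()},
                force_path=str(t["force_path"]),
            )
        )
    return TrialManifest(
        participant_id=str(doc["participant_id"]),
        mass_kg=mass,
        trials=trials,
        seed=doc.get("seed"),
    )


def write_manifest(manifest: TrialManifest, path: str | Path) -> None:
    doc = {
        "participant_id": manifest.participant_id,
        "mass_kg": float(manifest.mass_kg),
        "seed": manifest.seed,
        "trials": [
            {
                "trial_id": t.trial_id,
                "pace_label": t.pace_label,
                "target_velocity": float(t.target_velocity),
                "imu_paths": dict(t.imu_paths),
                "force_path": t.force_path,
            }
            for t in manifest.trials
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_trial(manifest: TrialManifest, spec: TrialSpec, base_dir: str | Path = "."):
    """Read the three IMU recordings and the force recording of one trial."""
    base = Path(base_dir)
    imus = {
        site: read_imu_csv(base / p, site=site) for site, p in spec.imu_paths.items()
    }
    force = read_force_csv(base / spec.force_path, manifest.mass_kg)
    return imus, force
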