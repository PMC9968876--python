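"""Inter-device synchronization and iterative clock-drift correction.

The insole and IMU clocks are aligned in two stages: a foot-stomp gives
the gross offset at the start of a session, and an iterative pass over
paired initial contacts removes residual drift by inserting or removing
zero-valued samples in swing-phase (zero-force) intervals of the kinetic
stream.  Stance-phase samples are never touched, so per-step impulse is
bit-invariant under correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import AlignmentError, ContractError, DetectionError, SyncError
from .io_store import ForceRecording, ImuRecording

#: residual tolerance for drift correction, seconds
DRIFT_TOL_S = 0.02
#: maximum IMU/force IC separation accepted during pairing, seconds
PAIRING_TOL_S = 0.1


@dataclass
class SyncResult:
    """Foot-stomp synchronization outcome (force clock minus IMU clock)."""

    offset_s: float
    stomp_time_imu: float
    stomp_time_force: float


@dataclass
class DriftReport:
    ic_pairs: list = field(default_factory=list)  # (imu_ic_s, force_ic_s) post-fix
    residuals_s: list = field(default_factory=list)
    samples_inserted: int = 0
    samples_removed: int = 0
    edits: list = field(default_factory=list)  # (pair_index, n_samples_signed)

    @property
    def max_residual_s(self) -> float:
        return float(np.max(np.abs(self.residuals_s))) if self.residuals_s else 0.0


def detect_stomp(
    imu_accel_mag: np.ndarray,
    force_sum_bw: np.ndarray,
    rate: float,
    search_s: float = 10.0,
    baseline_s: float = 0.5,
) -> SyncResult:
    """Locate the synchronization stomp in both streams.

    The IMU stomp time is the acceleration-magnitude peak within the
    search window; the force stomp time is the first force rise above
    5% BW.  Both transients must exceed 3x the pre-trial baseline MAD.
    """
    imu_accel_mag = np.asarray(imu_accel_mag, float)
    force_sum_bw = np.asarray(force_sum_bw, float)
    n_search = min(int(search_s * rate), len(imu_accel_mag), len(force_sum_bw))
    n_base = max(int(baseline_s * rate), 2)
    if n_search <= n_base:
        raise SyncError("streams too short to search for a stomp")

    a = imu_accel_mag[:n_search]
    base = a[:n_base]
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    thresh = med + 3.0 * max(mad, 1e-9)
    if np.max(a) <= thresh:
        raise SyncError(
            f"no IMU stomp transient above {thresh:.3g} in first {search_s:.0f} s"
        )
    imu_idx = int(np.argmax(a))

    f = force_sum_bw[:n_search]
    rise = np.nonzero(f > 0.05)[0]
    if rise.size == 0:
        raise SyncError("no force rise above 5% BW in the stomp search window")
    force_idx = int(rise[0])

    return SyncResult(
        offset_s=(force_idx - imu_idx) / rate,
        stomp_time_imu=imu_idx / rate,
        stomp_time_force=force_idx / rate,
    )


def detect_ic_from_imu(
    foot_imu: ImuRecording,
    rate: float,
    min_step_interval_s: float = 0.4,
    gyro_window_s: float = 0.15,
) -> np.ndarray:
    """Initial-contact times from one filtered foot IMU at 100 Hz.

    Heuristic: find resultant-acceleration impact peaks, then take the
    minimum of the sagittal-plane angular velocity (gyro y) in the window
    immediately preceding each peak.  Used only to drive clock-drift
    correction, never for reported kinetics.
    """
    mag = np.linalg.norm(foot_imu.accel, axis=1)
    duration = foot_imu.time[-1] - foot_imu.time[0] if len(foot_imu.time) else 0.0
    spread = float(np.percentile(mag, 99) - np.median(mag)) if mag.size else 0.0
    if spread <= 1e-9:
        raise DetectionError("foot acceleration carries no impact structure")
    peaks, _ = _signal.find_peaks(
        mag,
        prominence=0.3 * spread,
        height=float(np.median(mag)) + 0.3 * spread,
        distance=max(int(min_step_interval_s * rate), 1),
    )
    if peaks.size < 2 and duration > 10.0:
        raise DetectionError(
            f"only {peaks.size} impact events in a {duration:.0f} s trial"
        )
    w = max(int(gyro_window_s * rate), 1)
    gy = foot_imu.gyro[:, 1]
    ic_idx = []
    for p in peaks:
        lo = max(p - w, 0)
        ic_idx.append(lo + int(np.argmin(gy[lo : p + 1])))
    ic_times = foot_imu.time[np.asarray(ic_idx, int)]
    return np.asarray(ic_times, float)


def _pair_events(
    imu_ics: np.ndarray, force_ics: np.ndarray, tol: float, strict: bool
) -> list[tuple[int, int]]:
    """Greedy nearest-time pairing; returns (imu_index, force_index) pairs."""
    imu_ics = np.asarray(imu_ics, float)
    force_ics = np.asarray(force_ics, float)
    used = np.zeros(len(force_ics), bool)
    pairs = []
    orphans_imu = []
    for i, t in enumerate(imu_ics):
        free = np.nonzero(~used)[0]
        if free.size == 0:
            orphans_imu.append(t)
            continue
        j = free[np.argmin(np.abs(force_ics[free] - t))]
        if abs(force_ics[j] - t) <= tol:
            used[j] = True
            pairs.append((i, int(j)))
        else:
            orphans_imu.append(t)
    orphans_force = force_ics[~used].tolist()
    if strict and (orphans_imu or orphans_force):
        raise AlignmentError(
            f"unpairable initial contacts: imu={orphans_imu} force={orphans_force}"
        )
    return pairs


def correct_clock_drift(
    force: ForceRecording,
    imu_ics: np.ndarray,
    force_ics: np.ndarray,
    tol: float = DRIFT_TOL_S,
    pairing_tol: float = PAIRING_TOL_S,
    strict: bool = True,
) -> tuple[ForceRecording, DriftReport]:
    """Align force ICs to IMU ICs by editing zeros in preceding swing phases.

    Pairs ICs greedily by nearest time (within ``pairing_tol``), sweeps
    them in temporal order, and whenever a pair's residual exceeds
    ``tol`` inserts or removes zero-valued samples at the midpoint of the
    zero-force interval immediately preceding that force IC.  Downstream
    event times are recomputed after each edit, so correction of a slow
    linear drift accumulates along the trial.
    """
    rate = force.rate
    pairs = _pair_events(imu_ics, force_ics, pairing_tol, strict)
    pairs.sort(key=lambda ij: imu_ics[ij[0]])

    left = list(np.asarray(force.force_left, float))
    right = list(np.asarray(force.force_right, float))
    t0 = float(force.time[0])
    force_idx = [int(round((t - t0) * rate)) for t in np.asarray(force_ics, float)]

    report = DriftReport()
    shift = 0  # cumulative sample shift applied to downstream events
    for k, (i, j) in enumerate(pairs):
        cur_idx = force_idx[j] + shift
        residual = (t0 + cur_idx / rate) - imu_ics[i]
        n = 0
        if abs(residual) > tol:
            n = int(round(abs(residual) * rate))
            lo, hi = _preceding_zero_run(left, right, cur_idx)
            room = hi - lo - 1  # samples strictly inside the zero run
            if residual > 0:
                n = min(n, max(room, 0))
                mid = (lo + hi) // 2
                half = n // 2
                del left[mid - half : mid - half + n]
                del right[mid - half : mid - half + n]
                shift -= n
                report.samples_removed += n
                n = -n
            else:
                mid = (lo + hi + 1) // 2
                left[mid:mid] = [0.0] * n
                right[mid:mid] = [0.0] * n
                shift += n
                report.samples_inserted += n
        if n:
            report.edits.append((k, n))
        final_idx = force_idx[j] + shift
        final_residual = (t0 + final_idx / rate) - imu_ics[i]
        report.ic_pairs.append((float(imu_ics[i]), t0 + final_idx / rate))
        report.residuals_s.append(float(final_residual))

    n_out = len(left)
    corrected = ForceRecording(
        time=t0 + np.arange(n_out) / rate,
        force_left=np.asarray(left, float),
        force_right=np.asarray(right, float),
        rate=rate,
        body_weight=force.body_weight,
    )
    return corrected, report


def _preceding_zero_run(left: list, right: list, ic_idx: int) -> tuple[int, int]:
    """Bounds [lo, hi) of the zero-force run immediately before ``ic_idx``."""
    n = len(left)
    ic_idx = min(max(ic_idx, 0), n)
    hi = ic_idx
    # walk back over any leading edge of the stance (force already > 0)
    while hi > 0 and (left[hi - 1] + right[hi - 1]) > 0:
        hi -= 1
    lo = hi
    while lo > 0 and (left[lo - 1] + right[lo - 1]) == 0:
        lo -= 1
    if hi - lo < 3:
        raise ContractError(
            f"no usable swing interval before force IC at sample {ic_idx}"
        )
    return lo, hi
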