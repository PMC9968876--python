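"""Channel assembly and fixed-length window cutting.

The model input is a 24-column matrix: for each of the three mounting
sites the six raw inertial channels, followed by per-site acceleration
and angular-velocity resultant magnitudes (3 x (6 + 2) = 24).  Trials
are tiled into consecutive non-overlapping 4 s windows (400 samples at
100 Hz); estimated windows are concatenated back in order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .io_store import ForceRecording, ImuRecording

WINDOW_S = 4.0
RATE_HZ = 100.0
WINDOW_SAMPLES = int(WINDOW_S * RATE_HZ)
N_CHANNELS = 24

FORCE_ZERO_THRESHOLD_BW = 0.05

_RAW = ("ax", "ay", "az", "gx", "gy", "gz")
_SITES = ("left_foot", "right_foot", "sacrum")


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel names; identical across all trials of a run."""

    names: tuple = tuple(
        [f"{site}_{c}" for site in _SITES for c in _RAW]
        + [f"{site}_{m}" for site in _SITES for m in ("accel_mag", "gyro_mag")]
    )

    def __post_init__(self):
        if len(self.names) != N_CHANNELS:
            raise ContractError(f"channel layout must have {N_CHANNELS} entries")

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_LAYOUT = ChannelLayout()


@dataclass
class WindowPair:
    """One training example: 400 x 24 input window and 400 x 1 target (BW)."""

    x: np.ndarray
    y: np.ndarray
    trial_id: str
    start_index: int

    def __post_init__(self):
        if self.x.shape != (WINDOW_SAMPLES, N_CHANNELS):
            raise ContractError(
                f"window input must be {WINDOW_SAMPLES}x{N_CHANNELS}, got {self.x.shape}"
            )
        if self.y.shape[0] != WINDOW_SAMPLES:
            raise ContractError("window target must have 400 samples")
        if np.any(self.y < 0):
            raise ContractError("target force must be non-negative")


def assemble_channels(
    imu_set: dict[str, ImuRecording], layout: ChannelLayout = DEFAULT_LAYOUT
) -> np.ndarray:
    """Stack three 100 Hz IMU recordings into a T x 24 channel matrix."""
    missing = [s for s in _SITES if s not in imu_set]
    if missing:
        raise ContractError(f"missing IMU sites: {missing}")
    lengths = {len(imu_set[s].time) for s in _SITES}
    if len(lengths) != 1:
        raise ContractError(f"IMU recordings differ in length: {sorted(lengths)}")
    cols = {}
    for site in _SITES:
        rec = imu_set[site]
        for k, c in enumerate(_RAW[:3]):
            cols[f"{site}_{c}"] = rec.accel[:, k]
        for k, c in enumerate(_RAW[3:]):
            cols[f"{site}_{c}"] = rec.gyro[:, k]
        cols[f"{site}_accel_mag"] = np.linalg.norm(rec.accel, axis=1)
        cols[f"{site}_gyro_mag"] = np.linalg.norm(rec.gyro, axis=1)
    return np.column_stack([cols[name] for name in layout.names])


def sum_bilateral_force(force: ForceRecording) -> np.ndarray:
    """(left + right) / body weight, with sub-5%-BW values zeroed."""
    total = (force.force_left + force.force_right) / force.body_weight
    total = np.where(total < FORCE_ZERO_THRESHOLD_BW, 0.0, total)
    return total


def make_windows(
    channels: np.ndarray,
    force_bw: np.ndarray,
    trial_id: str = "",
    window_s: float = WINDOW_S,
    rate: float = RATE_HZ,
) -> list[WindowPair]:
    """Cut a trial into consecutive non-overlapping windows.

    The trailing remainder shorter than one window is dropped (with a
    warning); an input shorter than one window yields an empty list.
    """
    channels = np.asarray(channels, float)
    force_bw = np.asarray(force_bw, float)
    if channels.shape[0] != force_bw.shape[0]:
        raise ContractError("channels and force must have equal length")
    n = int(round(window_s * rate))
    t = channels.shape[0]
    n_windows = t // n
    if n_windows == 0:
        warnings.warn(
            f"trial {trial_id or '<unnamed>'}: {t} samples shorter than one "
            f"{n}-sample window; no windows produced",
            stacklevel=2,
        )
        return []
    dropped = t - n_windows * n
    if dropped:
        warnings.warn(
            f"trial {trial_id or '<unnamed>'}: dropping {dropped} trailing samples",
            stacklevel=2,
        )
    return [
        WindowPair(
            x=channels[k * n : (k + 1) * n],
            y=force_bw[k * n : (k + 1) * n],
            trial_id=trial_id,
            start_index=k * n,
        )
        for k in range(n_windows)
    ]


def concatenate_estimates(
    window_outputs: list[tuple[int, np.ndarray]],
    trial_length: int,
) -> np.ndarray:
    """Reassemble per-window estimates into a trial-length waveform.

    ``window_outputs`` is a list of (start_index, 400-vector) ordered by
    start index; the uncovered tail (samples dropped at windowing time)
    is zero-filled.
    """
    out = np.zeros(trial_length)
    expected_start = 0
    for start, y in window_outputs:
        y = np.asarray(y, float).reshape(-1)
        if start != expected_start:
            raise ContractError(
                f"windows must be consecutive and ordered: expected start "
                f"{expected_start}, got {start}"
            )
        if start + len(y) > trial_length:
            raise ContractError("window extends past the declared trial length")
        out[start : start + len(y)] = y
        expected_start = start + len(y)
    return out
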