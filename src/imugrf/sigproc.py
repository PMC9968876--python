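"""Resampling and zero-lag Butterworth low-pass filtering.

Defaults follow the pipeline constants: inertial channels get a 4th-order
35 Hz design, force channels a 2nd-order 20 Hz design, each applied
forward and backward (zero phase, squared magnitude response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ContractError


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth description.

    ``order`` is the stated design order.  When ``order_is_two_pass`` is
    true the stated order is interpreted as the *effective* (two-pass)
    order and the design order is halved before building the filter.
    """

    order: int
    cutoff_hz: float
    kind: str = "lowpass"
    order_is_two_pass: bool = False

    def __post_init__(self):
        if self.order not in (2, 4):
            raise ContractError("filter order must be 2 or 4")
        if self.cutoff_hz <= 0:
            raise ContractError("cutoff must be positive")
        if self.kind != "lowpass":
            raise ContractError("only lowpass filters are supported")

    @property
    def design_order(self) -> int:
        return self.order // 2 if self.order_is_two_pass else self.order


IMU_FILTER = FilterSpec(order=4, cutoff_hz=35.0)
FORCE_FILTER = FilterSpec(order=2, cutoff_hz=20.0)


def lowpass_zero_lag(series: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase, unit DC gain).

    Works on 1-D series or 2-D arrays (filtered along axis 0).
    """
    series = np.asarray(series, float)
    n = series.shape[0]
    order = spec.design_order
    padlen = 3 * order
    if n <= padlen:
        raise ContractError(
            f"series of length {n} too short for order-{order} zero-lag filtering"
        )
    if spec.cutoff_hz >= rate / 2:
        raise ContractError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, spec.cutoff_hz, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0, padtype="even", padlen=padlen)


def two_pass_magnitude(
    spec: FilterSpec, freq_hz: float, rate: float | None = None
) -> float:
    """Closed-form steady-state gain of the forward-backward filter.

    With ``rate`` omitted this is the analog Butterworth form
    1 / (1 + (f/fc)^(2n)), accurate when the sample rate is large
    relative to the probe frequency.  With ``rate`` given, the bilinear
    frequency warping of the digital design is included (the response
    scipy's ``butter`` actually realizes), which matters for probes
    approaching the Nyquist frequency.
    """
    n = spec.design_order
    if rate is None:
        ratio = freq_hz / spec.cutoff_hz
    else:
        ratio = np.tan(np.pi * freq_hz / rate) / np.tan(
            np.pi * spec.cutoff_hz / rate
        )
    return 1.0 / (1.0 + ratio ** (2 * n))


def resample_to(
    time: np.ndarray,
    series: np.ndarray,
    target_rate: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample onto a uniform grid at ``target_rate`` covering the source span.

    A steep (order 8, two-pass) anti-alias low-pass at 0.46 * target_rate
    is applied before rate reduction so pass-band content below ~0.4 of
    the target rate is preserved, then linear interpolation moves samples
    onto the target grid (the device grids are not phase locked).
    Upsampling is not supported.
    """
    time = np.asarray(time, float)
    series = np.asarray(series, float)
    if len(time) < 2:
        raise ContractError("need at least two samples to resample")
    source_rate = 1.0 / float(np.median(np.diff(time)))
    if target_rate > source_rate * (1 + 1e-9):
        raise ContractError(
            f"upsampling not supported ({source_rate:.1f} -> {target_rate:.1f} Hz)"
        )
    if target_rate < source_rate * (1 - 1e-9):
        sos = signal.butter(
            8, 0.46 * target_rate, btype="low", fs=source_rate, output="sos"
        )
        series = signal.sosfiltfilt(sos, series, axis=0)
    span = time[-1] - time[0]
    n_out = int(np.floor(span * target_rate + 1e-9)) + 1
    new_time = time[0] + np.arange(n_out) / target_rate
    if series.ndim == 1:
        new_series = np.interp(new_time, time, series)
    else:
        new_series = np.column_stack(
            [np.interp(new_time, time, series[:, j]) for j in range(series.shape[1])]
        )
    return new_time, new_series
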