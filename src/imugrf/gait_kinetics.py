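"""Gait-event detection and kinetic-variable extraction from GRF waveforms.

All forces are in body weights (BW) on a uniform grid.  Initial contact
is the first sample of a contiguous run with force > 5% BW, toe off the
last such sample (inclusive indexing, strict thresholds).  Estimated
waveforms are cleaned first: low-pass filtered like the measured force,
sub-threshold values zeroed, and contacts shorter than 0.050 s removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import ContractError
from .sigproc import FORCE_FILTER, FilterSpec, lowpass_zero_lag

FORCE_THRESHOLD_BW = 0.05
MIN_CONTACT_S = 0.050
#: plausible running contact-time band, seconds
CONTACT_BAND_S = (0.05, 0.6)


@dataclass(frozen=True)
class StanceEvents:
    """One stance phase: initial contact and toe off."""

    ic_idx: int
    to_idx: int
    rate: float

    @property
    def ic_s(self) -> float:
        return self.ic_idx / self.rate

    @property
    def to_s(self) -> float:
        return self.to_idx / self.rate

    def __post_init__(self):
        if self.to_idx <= self.ic_idx:
            raise ContractError("toe off must come after initial contact")


@dataclass
class KineticSummary:
    contact_time_s: float
    stance_average_bw: float
    impulse_bw_s: float
    peak_bw: float
    loading_rate_bw_s: float


def postprocess_estimate(
    y_hat: np.ndarray,
    rate: float = 100.0,
    spec: FilterSpec = FORCE_FILTER,
) -> np.ndarray:
    """Clean a concatenated trial-length estimate.

    Applies the measured-force filter (2nd order, 20 Hz, zero lag), zeroes
    values below 5% BW, then zeroes contiguous supra-threshold runs
    shorter than 0.050 s (sensor-noise blips, not running foot contacts).
    """
    y = np.asarray(y_hat, float).reshape(-1)
    if np.any(y != 0):
        y = lowpass_zero_lag(y, spec, rate)
    y = np.where(y < FORCE_THRESHOLD_BW, 0.0, y)
    min_run = int(round(MIN_CONTACT_S * rate))
    for lo, hi in _runs_above_zero(y):
        if hi - lo < min_run:
            y[lo:hi] = 0.0
    return y


def _runs_above_zero(y: np.ndarray):
    """Half-open [lo, hi) bounds of contiguous positive runs."""
    mask = y > 0
    if not mask.any():
        return
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = [0] if mask[0] else []
    starts += list(edges[~mask[edges]] + 1)
    ends = list(edges[mask[edges]] + 1)
    if mask[-1]:
        ends.append(len(y))
    yield from zip(starts, ends)


def detect_stances(force_bw: np.ndarray, rate: float) -> list[StanceEvents]:
    """One StanceEvents per contiguous run of force > 5% BW."""
    force_bw = np.asarray(force_bw, float)
    mask = force_bw > FORCE_THRESHOLD_BW
    events = []
    for lo, hi in _runs_above_zero(mask.astype(float)):
        if hi - lo >= 2:
            events.append(StanceEvents(ic_idx=lo, to_idx=hi - 1, rate=rate))
    return events


def exclude_boundary_stances(
    events: list[StanceEvents], n_samples: int
) -> list[StanceEvents]:
    """Drop stances touching the first or last sample (truncated by windowing)."""
    return [e for e in events if e.ic_idx > 0 and e.to_idx < n_samples - 1]


def contact_time(ev: StanceEvents) -> float:
    return ev.to_s - ev.ic_s


def find_impact_peak(
    force_bw: np.ndarray,
    ev: StanceEvents,
    rate: float,
    region_fraction: float = 0.35,
    min_prominence_bw: float = 0.05,
) -> float | None:
    """First early-stance local maximum, or None.

    Searches the first 35% of stance for a local maximum with prominence
    of at least 0.05 BW; a monotone rise to the active peak yields None.
    """
    span = np.asarray(force_bw[ev.ic_idx : ev.to_idx + 1], float)
    n_region = int(np.ceil(len(span) * region_fraction))
    if n_region < 3:
        return None
    peaks, props = _signal.find_peaks(span, prominence=min_prominence_bw)
    early = peaks[peaks < n_region]
    if early.size == 0:
        return None
    return (ev.ic_idx + int(early[0])) / rate


def average_loading_rate(
    force_bw: np.ndarray,
    ev: StanceEvents,
    rate: float,
    strategy: str = "impact_peak",
) -> float:
    """Average slope of the rising GRF, BW/s.

    ``impact_peak`` (default): secant slope over the middle 60% (20%-80%)
    of the IC -> impact-peak interval; falls back to ``fixed_window``
    when no impact peak exists.  ``fixed_window``: secant slope between
    10% and 40% of contact time.  On a uniform grid the mean of pointwise
    slopes telescopes to the secant slope, so the secant form is exact.
    """
    force_bw = np.asarray(force_bw, float)
    if strategy not in ("impact_peak", "fixed_window"):
        raise ContractError(f"unknown loading-rate strategy {strategy!r}")
    if strategy == "impact_peak":
        peak_t = find_impact_peak(force_bw, ev, rate)
        if peak_t is None:
            return average_loading_rate(force_bw, ev, rate, "fixed_window")
        peak_idx = int(round(peak_t * rate))
        lo = ev.ic_idx + (peak_idx - ev.ic_idx) * 0.2
        hi = ev.ic_idx + (peak_idx - ev.ic_idx) * 0.8
    else:
        n_contact = ev.to_idx - ev.ic_idx
        lo = ev.ic_idx + 0.10 * n_contact
        hi = ev.ic_idx + 0.40 * n_contact
    i_lo, i_hi = int(round(lo)), int(round(hi))
    if i_hi - i_lo < 1:
        raise ContractError("loading-rate interval shorter than 2 samples")
    return float((force_bw[i_hi] - force_bw[i_lo]) / ((i_hi - i_lo) / rate))


def stance_kinetics(
    force_bw: np.ndarray,
    ev: StanceEvents,
    rate: float,
    loading_rate_strategy: str = "impact_peak",
) -> KineticSummary:
    """Contact time, stance average, impulse, peak and loading rate."""
    force_bw = np.asarray(force_bw, float)
    if ev.to_idx >= len(force_bw):
        raise ContractError("stance extends past the waveform")
    span = force_bw[ev.ic_idx : ev.to_idx + 1]
    if len(span) < 3:
        raise ContractError("degenerate stance: fewer than 3 samples")
    return KineticSummary(
        contact_time_s=contact_time(ev),
        stance_average_bw=float(np.mean(span)),
        impulse_bw_s=float(np.trapezoid(span, dx=1.0 / rate)),
        peak_bw=float(np.max(span)),
        loading_rate_bw_s=average_loading_rate(
            force_bw, ev, rate, loading_rate_strategy
        ),
    )
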