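"""Agreement statistics between measured and estimated GRF outputs.

Trial-level values feed regression, correlation and Bland-Altman
analyses; per-velocity tables aggregate stance/waveform RMSE, gait-event
differences and per-variable RMSE (mean +/- SD, single-trial bins report
SD 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .gait_kinetics import KineticSummary, StanceEvents

KINETIC_VARIABLES = (
    "contact_time_s",
    "stance_average_bw",
    "impulse_bw_s",
    "peak_bw",
    "loading_rate_bw_s",
)


@dataclass
class TrialAgreement:
    """Per-trial agreement inputs for the summary tables."""

    trial_id: str
    velocity: float
    stance_rmse_bw: float
    waveform_rmse_bw: float
    ic_diff_s: float
    to_diff_s: float
    #: variable name -> (measured, estimated) trial means
    kinetics: dict = field(default_factory=dict)


@dataclass
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    r2: float | None = None
    strength: str | None = None
    slope: float | None = None
    intercept: float | None = None
    slope_ci: tuple | None = None
    intercept_ci: tuple | None = None
    n: int = 0


def waveform_rmse(measured: np.ndarray, estimated: np.ndarray) -> float:
    """RMSE over every sample of the trial, swing included."""
    measured = np.asarray(measured, float)
    estimated = np.asarray(estimated, float)
    if measured.shape != estimated.shape:
        raise ContractError("measured and estimated must have equal length")
    return float(np.sqrt(np.mean((measured - estimated) ** 2)))


def stance_rmse(
    measured: np.ndarray,
    estimated: np.ndarray,
    stances_measured: list[StanceEvents],
) -> float | None:
    """Per-stance RMSE over measured stance spans, averaged over stances."""
    measured = np.asarray(measured, float)
    estimated = np.asarray(estimated, float)
    if measured.shape != estimated.shape:
        raise ContractError("measured and estimated must have equal length")
    if not stances_measured:
        return None
    per_stance = []
    for ev in stances_measured:
        m = measured[ev.ic_idx : ev.to_idx + 1]
        e = estimated[ev.ic_idx : ev.to_idx + 1]
        per_stance.append(np.sqrt(np.mean((m - e) ** 2)))
    return float(np.mean(per_stance))


def event_differences(
    measured_events: list[StanceEvents],
    estimated_events: list[StanceEvents],
    pairing_tol: float = 0.1,
) -> dict:
    """Signed measured - estimated IC/TO differences after nearest pairing.

    Positive values mean the estimated event precedes the measured one.
    Unpaired events on either side are counted, not dropped silently.
    """
    m_ic = np.array([e.ic_s for e in measured_events])
    e_ic = np.array([e.ic_s for e in estimated_events])
    used = np.zeros(len(e_ic), bool)
    ic_diffs, to_diffs = [], []
    unpaired_measured = 0
    for i, t in enumerate(m_ic):
        free = np.nonzero(~used)[0]
        if free.size == 0:
            unpaired_measured += 1
            continue
        j = free[np.argmin(np.abs(e_ic[free] - t))]
        if abs(e_ic[j] - t) <= pairing_tol:
            used[j] = True
            ic_diffs.append(measured_events[i].ic_s - estimated_events[j].ic_s)
            to_diffs.append(measured_events[i].to_s - estimated_events[j].to_s)
        else:
            unpaired_measured += 1
    return {
        "ic_diffs": np.asarray(ic_diffs),
        "to_diffs": np.asarray(to_diffs),
        "unpaired_measured": unpaired_measured,
        "unpaired_estimated": int(np.sum(~used)),
    }


def bland_altman(
    estimated_values: np.ndarray, measured_values: np.ndarray
) -> AgreementReport:
    """Bias and 1.96-SD limits of agreement for estimated - measured."""
    est = np.asarray(estimated_values, float)
    mea = np.asarray(measured_values, float)
    if est.shape != mea.shape:
        raise ContractError("paired value vectors must have equal length")
    if est.size < 3:
        raise ContractError("Bland-Altman needs at least 3 paired values")
    diffs = est - mea
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return AgreementReport(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=est.size
    )


def strength_label(r2: float) -> str:
    if r2 >= 0.8:
        return "strong"
    if r2 >= 0.5:
        return "moderate"
    if r2 >= 0.3:
        return "weak"
    return "negligible"


def correlation_r2(
    estimated_values: np.ndarray, measured_values: np.ndarray
) -> tuple[float, str] | None:
    """Squared Pearson correlation with its strength band, or None."""
    est = np.asarray(estimated_values, float)
    mea = np.asarray(measured_values, float)
    if est.size < 3:
        raise ContractError("correlation needs at least 3 paired values")
    if np.std(est) == 0 or np.std(mea) == 0:
        return None
    r = stats.pearsonr(est, mea).statistic
    r2 = float(r * r)
    return r2, strength_label(r2)


def regression_with_ci(
    estimated_values: np.ndarray,
    measured_values: np.ndarray,
    alpha: float = 0.05,
) -> AgreementReport:
    """OLS of estimated on measured with t-based 95% CIs, plus r2 and LoA."""
    est = np.asarray(estimated_values, float)
    mea = np.asarray(measured_values, float)
    if est.size < 3:
        raise ContractError("regression needs at least 3 paired values")
    res = stats.linregress(mea, est)
    dof = est.size - 2
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    ba = bland_altman(est, mea)
    corr = correlation_r2(est, mea)
    r2, label = corr if corr is not None else (None, None)
    return AgreementReport(
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        r2=r2,
        strength=label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        n=est.size,
    )


def kinetic_rmse(measured: float | np.ndarray, estimated: float | np.ndarray) -> float:
    """Trial-level RMSE of a kinetic variable over its stances."""
    m = np.atleast_1d(np.asarray(measured, float))
    e = np.atleast_1d(np.asarray(estimated, float))
    n = min(len(m), len(e))
    if n == 0:
        return math.nan
    return float(np.sqrt(np.mean((m[:n] - e[:n]) ** 2)))


def per_velocity_summary(trial_agreements: list[TrialAgreement]) -> pd.DataFrame:
    """Mean +/- SD of every agreement metric grouped by target velocity.

    SD uses the n-1 denominator; single-trial bins report SD 0.
    """
    if not trial_agreements:
        return pd.DataFrame()
    rows = []
    for ta in trial_agreements:
        row = {
            "velocity": ta.velocity,
            "stance_rmse_bw": ta.stance_rmse_bw,
            "waveform_rmse_bw": ta.waveform_rmse_bw,
            "ic_diff_s": ta.ic_diff_s,
            "to_diff_s": ta.to_diff_s,
        }
        for var in KINETIC_VARIABLES:
            if var in ta.kinetics:
                mea, est = ta.kinetics[var]
                row[f"{var}_rmse"] = kinetic_rmse(mea, est)
        rows.append(row)
    df = pd.DataFrame(rows)
    grouped = df.groupby("velocity")
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    out = pd.concat(
        {"mean": mean, "sd": sd}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1)
    out.columns = [f"{metric}_{stat}" for metric, stat in out.columns]
    return out.reset_index()
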