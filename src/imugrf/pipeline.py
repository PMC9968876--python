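"""End-to-end orchestration: preprocess -> windows -> LOOCV -> agreement.

Per-trial preprocessing chain: resample inertial channels to 100 Hz,
zero-lag low-pass both modalities (35 Hz/4th order inertial, 20 Hz/2nd
order force), foot-stomp synchronization, zero-threshold the force,
iterative clock-drift correction, channel assembly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement_eval, gait_kinetics, seq2seq_model, sync_align, windowing
from .io_store import (
    ForceRecording,
    ImuRecording,
    TrialManifest,
    TrialSpec,
    load_trial,
)
from .seq2seq_model import ModelConfig, TrialData
from .sigproc import FORCE_FILTER, IMU_FILTER, FilterSpec, lowpass_zero_lag, resample_to

log = logging.getLogger("imugrf")


@dataclass
class PipelineConfig:
    """All tunable constants; defaults reproduce the published pipeline."""

    imu_filter: FilterSpec = IMU_FILTER
    force_filter: FilterSpec = FORCE_FILTER
    working_rate_hz: float = 100.0
    window_s: float = 4.0
    force_threshold_bw: float = 0.05
    min_contact_s: float = 0.050
    drift_tol_s: float = 0.02
    loading_rate_strategy: str = "impact_peak"
    #: drop gait events within this many seconds after the stomp
    sync_guard_s: float = 1.5
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0


def preprocess_trial(
    manifest: TrialManifest,
    spec: TrialSpec,
    base_dir: str | Path = ".",
    config: PipelineConfig | None = None,
) -> tuple[TrialData, sync_align.DriftReport]:
    """Produce one synchronized, filtered, drift-corrected TrialData."""
    config = config or PipelineConfig()
    rate = config.working_rate_hz
    imus_raw, force = load_trial(manifest, spec, base_dir)

    imus: dict[str, ImuRecording] = {}
    for site, rec in imus_raw.items():
        data = np.column_stack([rec.accel, rec.gyro])
        t100, data100 = resample_to(rec.time, data, target_rate=rate)
        data100 = lowpass_zero_lag(data100, config.imu_filter, rate)
        imus[site] = ImuRecording(
            site=site,
            time=t100,
            accel=data100[:, :3],
            gyro=data100[:, 3:],
            rate=rate,
        )

    f_left = lowpass_zero_lag(force.force_left, config.force_filter, force.rate)
    f_right = lowpass_zero_lag(force.force_right, config.force_filter, force.rate)

    # foot-stomp synchronization on the sacrum accelerometer
    accel_mag = np.linalg.norm(imus["sacrum"].accel, axis=1)
    sum_bw = (f_left + f_right) / force.body_weight
    sync = sync_align.detect_stomp(accel_mag, sum_bw, rate)
    force_time = force.time - sync.offset_s

    # move the force onto the common 100 Hz IMU grid
    grid = imus["sacrum"].time
    left_g = np.interp(grid, force_time, f_left, left=0.0, right=0.0)
    right_g = np.interp(grid, force_time, f_right, left=0.0, right=0.0)
    # zero-threshold (sub-5%-BW readings are noise) so swing phases are exact zeros
    swing = (left_g + right_g) / force.body_weight < config.force_threshold_bw
    left_g[swing] = 0.0
    right_g[swing] = 0.0
    force_g = ForceRecording(
        time=grid,
        force_left=left_g,
        force_right=right_g,
        rate=rate,
        body_weight=force.body_weight,
    )

    guard = sync.stomp_time_imu + config.sync_guard_s
    imu_ics = np.sort(
        np.concatenate(
            [
                sync_align.detect_ic_from_imu(imus["left_foot"], rate),
                sync_align.detect_ic_from_imu(imus["right_foot"], rate),
            ]
        )
    )
    imu_ics = imu_ics[imu_ics > guard]
    force_bw = windowing.sum_bilateral_force(force_g)
    force_events = gait_kinetics.detect_stances(force_bw, rate)
    force_ics = np.array(
        [grid[0] + e.ic_s for e in force_events if grid[0] + e.ic_s > guard]
    )

    corrected, report = sync_align.correct_clock_drift(
        force_g,
        imu_ics,
        force_ics,
        tol=config.drift_tol_s,
        strict=False,
    )

    t = min(len(grid), len(corrected.time))
    channels = windowing.assemble_channels(
        {s: _truncate_imu(r, t) for s, r in imus.items()}
    )
    force_bw = windowing.sum_bilateral_force(corrected)[:t]
    trial = TrialData(
        trial_id=spec.trial_id,
        participant_id=manifest.participant_id,
        channels=channels,
        force_bw=force_bw,
        velocity=spec.target_velocity,
    )
    return trial, report


def _truncate_imu(rec: ImuRecording, n: int) -> ImuRecording:
    return dataclasses.replace(
        rec, time=rec.time[:n], accel=rec.accel[:n], gyro=rec.gyro[:n]
    )


def preprocess_cohort(
    manifests: list[TrialManifest],
    base_dir: str | Path = ".",
    config: PipelineConfig | None = None,
) -> tuple[list[TrialData], dict]:
    """Preprocess every trial; failures are recorded, not fatal."""
    trials, reports = [], {}
    for manifest in manifests:
        for spec in manifest.trials:
            try:
                trial, report = preprocess_trial(manifest, spec, base_dir, config)
            except Exception as exc:  # keep other trials going
                log.warning("trial %s failed preprocessing: %s", spec.trial_id, exc)
                reports[spec.trial_id] = exc
                continue
            trials.append(trial)
            reports[spec.trial_id] = report
    return trials, reports


def _trial_kinetics(
    force_bw: np.ndarray, rate: float, strategy: str
) -> tuple[list, list]:
    events = gait_kinetics.detect_stances(force_bw, rate)
    events = gait_kinetics.exclude_boundary_stances(events, len(force_bw))
    summaries = []
    for ev in events:
        try:
            summaries.append(
                gait_kinetics.stance_kinetics(force_bw, ev, rate, strategy)
            )
        except Exception:
            summaries.append(None)
    keep = [i for i, s in enumerate(summaries) if s is not None]
    return [events[i] for i in keep], [summaries[i] for i in keep]


def evaluate_agreement(
    trials: list[TrialData],
    estimates: dict[str, np.ndarray],
    config: PipelineConfig | None = None,
) -> tuple[list[agreement_eval.TrialAgreement], dict]:
    """Per-trial agreement records plus per-variable trial-mean pairs."""
    config = config or PipelineConfig()
    rate = config.working_rate_hz
    strategy = config.loading_rate_strategy
    agreements = []
    trial_means: dict[str, list] = {v: [] for v in agreement_eval.KINETIC_VARIABLES}
    for trial in trials:
        if trial.trial_id not in estimates:
            continue
        est = gait_kinetics.postprocess_estimate(
            estimates[trial.trial_id], rate, config.force_filter
        )
        mea = trial.force_bw
        m_events, m_kin = _trial_kinetics(mea, rate, strategy)
        e_events, e_kin = _trial_kinetics(est, rate, strategy)
        if not m_events:
            log.warning("trial %s: no measured stances", trial.trial_id)
            continue
        diffs = agreement_eval.event_differences(m_events, e_events)
        kinetics = {}
        pairs = _pair_stances(m_events, e_events)
        for var in agreement_eval.KINETIC_VARIABLES:
            m_vals = np.array([getattr(m_kin[i], var) for i, _ in pairs])
            e_vals = np.array([getattr(e_kin[j], var) for _, j in pairs])
            kinetics[var] = (m_vals, e_vals)
            if len(m_vals):
                trial_means[var].append(
                    (
                        trial.trial_id,
                        trial.velocity,
                        float(np.mean(m_vals)),
                        float(np.mean(e_vals)),
                    )
                )
        agreements.append(
            agreement_eval.TrialAgreement(
                trial_id=trial.trial_id,
                velocity=trial.velocity,
                stance_rmse_bw=agreement_eval.stance_rmse(mea, est, m_events),
                waveform_rmse_bw=agreement_eval.waveform_rmse(mea, est),
                ic_diff_s=(
                    float(np.mean(diffs["ic_diffs"])) if len(diffs["ic_diffs"]) else np.nan
                ),
                to_diff_s=(
                    float(np.mean(diffs["to_diffs"])) if len(diffs["to_diffs"]) else np.nan
                ),
                kinetics=kinetics,
            )
        )
    return agreements, trial_means


def _pair_stances(m_events, e_events, tol: float = 0.1) -> list[tuple[int, int]]:
    used = np.zeros(len(e_events), bool)
    pairs = []
    e_ic = np.array([e.ic_s for e in e_events])
    for i, ev in enumerate(m_events):
        free = np.nonzero(~used)[0]
        if free.size == 0:
            break
        j = free[np.argmin(np.abs(e_ic[free] - ev.ic_s))]
        if abs(e_ic[j] - ev.ic_s) <= tol:
            used[j] = True
            pairs.append((i, int(j)))
    return pairs


def run_loocv(
    trials: list[TrialData],
    config: PipelineConfig | None = None,
) -> dict[str, np.ndarray]:
    config = config or PipelineConfig()
    return seq2seq_model.loocv(trials, config.model)


def write_reports(
    agreements: list[agreement_eval.TrialAgreement],
    trial_means: dict,
    out_dir: str | Path,
) -> None:
    """Summary tables (per velocity) and per-variable agreement statistics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = agreement_eval.per_velocity_summary(agreements)
    summary.to_csv(out_dir / "per_velocity_summary.csv", index=False)

    rows = []
    for var, entries in trial_means.items():
        if len(entries) < 3:
            continue
        mea = np.array([m for _, _, m, _ in entries])
        est = np.array([e for _, _, _, e in entries])
        report = agreement_eval.regression_with_ci(est, mea)
        rows.append(
            {
                "variable": var,
                "bias": report.bias,
                "loa_low": report.loa_low,
                "loa_high": report.loa_high,
                "r2": report.r2,
                "label": report.strength,
                "n": report.n,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "variable_agreement.csv", index=False)
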