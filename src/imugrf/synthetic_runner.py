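"""Synthetic paired insole-force / tri-IMU running data with ground truth.

The force model is a half-sine active peak per step (amplitude chosen so
the stride-averaged summed force is exactly 1 BW, the steady-running
impulse-momentum constraint) with an optional early Gaussian impact
bump.  Contact time shortens and step frequency rises linearly with
velocity, with a flight phase required at every configured velocity.
The sacrum vertical acceleration is an exact affine function of the
summed force before noise, so the inertial-to-force mapping is learnable
by construction and model-training tests are meaningful.

Timestamps can be scaled by a parts-per-million factor to emulate the
insole clock drifting against the IMU clock.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_store import (
    GRAVITY,
    ForceRecording,
    ImuRecording,
    TrialManifest,
    TrialSpec,
    write_force_csv,
    write_imu_csv,
    write_manifest,
)

METERS_PER_MILE = 1609.34
ACCEL_CLIP_MS2 = 16.0 * GRAVITY  # device range 0-16 g

#: session layout when a synchronization stomp is included
STOMP_TIME_S = 1.0
STOMP_DURATION_S = 0.08
RUN_START_S = 3.0


@dataclass
class RunnerProfile:
    """Per-participant gait and sensor-noise parameters.

    Contact time Tc(v) = tc_a - tc_b * v and step frequency
    f(v) = sf_c + sf_d * v; defaults give a flight phase over the whole
    2.0-6.0 m/s working range.
    """

    participant_id: str
    mass_kg: float
    tc_a: float = 0.38
    tc_b: float = 0.03
    sf_c: float = 2.5
    sf_d: float = 0.12
    impact_amplitude_bw: float = 0.0
    force_noise_n: float = 0.0
    imu_noise_ms2: float = 0.0
    gyro_noise_rads: float = 0.0
    drift_ppm: float = 0.0

    def contact_time(self, velocity: float) -> float:
        return self.tc_a - self.tc_b * velocity

    def step_frequency(self, velocity: float) -> float:
        return self.sf_c + self.sf_d * velocity

    @property
    def body_weight(self) -> float:
        return self.mass_kg * GRAVITY


@dataclass
class StepTruth:
    """Analytic per-step values.

    ``start_s`` is the instant force leaves exact zero (waveform phase);
    ``ic_s``/``to_s`` are the 5% BW threshold crossings, matching the
    event definition used on measured waveforms.  Kinetic values are
    dense numeric evaluations of the continuous step waveform over the
    threshold-crossing span.
    """

    start_s: float
    ic_s: float
    to_s: float
    foot: str  # "left" | "right"
    contact_time_s: float
    stance_average_bw: float
    peak_bw: float
    impulse_bw_s: float
    loading_rate_bw_s: float


@dataclass
class GroundTruth:
    """Analytic per-step values consistent with the emitted waveform."""

    velocity: float
    contact_time_s: float
    step_period_s: float
    amplitude_bw: float
    impact_amplitude_bw: float
    run_start_s: float
    duration_s: float
    stomp_time_s: float | None
    drift_ppm: float
    steps: list = field(default_factory=list)

    def step_force_bw(self, t_rel: np.ndarray) -> np.ndarray:
        """Continuous single-step force, t_rel measured from initial contact."""
        tc = self.contact_time_s
        f = np.where(
            (t_rel >= 0) & (t_rel <= tc),
            self.amplitude_bw * np.sin(np.pi * np.clip(t_rel, 0, tc) / tc),
            0.0,
        )
        if self.impact_amplitude_bw:
            center, sigma = 0.13 * tc, 0.03 * tc
            bump = self.impact_amplitude_bw * np.exp(
                -0.5 * ((t_rel - center) / sigma) ** 2
            )
            f = f + np.where((t_rel >= 0) & (t_rel <= tc), bump, 0.0)
        return f

    def foot_force_bw(self, t: np.ndarray, foot: str) -> np.ndarray:
        out = np.zeros_like(t, dtype=float)
        tc = self.contact_time_s
        for step in self.steps:
            if step.foot != foot:
                continue
            sel = (t >= step.start_s) & (t <= step.start_s + tc)
            if sel.any():
                out[sel] += self.step_force_bw(t[sel] - step.start_s)
        return out

    def force_bw_at(self, t: np.ndarray) -> np.ndarray:
        """Noise-free summed (both feet) force in BW at arbitrary times."""
        return self.foot_force_bw(t, "left") + self.foot_force_bw(t, "right")


def pace_to_velocity(pace_min_per_mile: float | str) -> float:
    """Minutes-per-mile pace to m/s (accepts 8.5 or "8:30")."""
    if isinstance(pace_min_per_mile, str):
        parts = pace_min_per_mile.split(":")
        minutes = float(parts[0])
        seconds = float(parts[1]) if len(parts) > 1 else 0.0
        pace_s = minutes * 60 + seconds
    else:
        pace_s = float(pace_min_per_mile) * 60
    if pace_s <= 0:
        raise ContractError("pace must be positive")
    return METERS_PER_MILE / pace_s


THRESHOLD_BW = 0.05


def _analytic_step_truth(gt: GroundTruth, start: float, foot: str) -> StepTruth:
    """Dense numeric evaluation of one step's kinetic ground truth.

    Events and kinetics refer to the 5% BW threshold-crossing span, the
    same convention applied to measured waveforms.
    """
    tc = gt.contact_time_s
    t_rel = np.linspace(0, tc, 8001)
    f = gt.step_force_bw(t_rel)
    above = np.nonzero(f > THRESHOLD_BW)[0]
    t_lo, t_hi = t_rel[above[0]], t_rel[above[-1]]
    span = slice(above[0], above[-1] + 1)
    contact = t_hi - t_lo
    # fixed-window loading rate: secant between 10% and 40% of contact time
    f10 = float(gt.step_force_bw(np.array([t_lo + 0.10 * contact]))[0])
    f40 = float(gt.step_force_bw(np.array([t_lo + 0.40 * contact]))[0])
    return StepTruth(
        start_s=start,
        ic_s=start + t_lo,
        to_s=start + t_hi,
        foot=foot,
        contact_time_s=contact,
        stance_average_bw=float(np.mean(f[span])),
        peak_bw=float(np.max(f)),
        impulse_bw_s=float(np.trapezoid(f[span], t_rel[span])),
        loading_rate_bw_s=(f40 - f10) / (0.30 * contact),
    )


def simulate_force(
    profile: RunnerProfile,
    velocity: float,
    duration_s: float,
    rate: float = 100.0,
    seed: int = 0,
    include_stomp: bool = False,
) -> tuple[ForceRecording, GroundTruth]:
    """Generate a bilateral insole recording plus its analytic ground truth."""
    if duration_s < 10:
        raise ContractError("simulated trials must last at least 10 s")
    tc = profile.contact_time(velocity)
    t_step = 1.0 / profile.step_frequency(velocity)
    if tc >= t_step:
        raise ContractError(
            f"no flight phase at v={velocity} (Tc={tc:.3f} >= Tstep={t_step:.3f}); "
            "walking is not modeled"
        )
    amplitude = (np.pi / 2.0) * (t_step / tc)
    run_start = RUN_START_S if include_stomp else 0.0
    gt = GroundTruth(
        velocity=velocity,
        contact_time_s=tc,
        step_period_s=t_step,
        amplitude_bw=amplitude,
        impact_amplitude_bw=profile.impact_amplitude_bw,
        run_start_s=run_start,
        duration_s=duration_s,
        stomp_time_s=STOMP_TIME_S if include_stomp else None,
        drift_ppm=profile.drift_ppm,
    )
    k = 0
    while True:
        ic = run_start + k * t_step
        if ic + tc > duration_s - 0.2:
            break
        foot = "left" if k % 2 == 0 else "right"
        gt.steps.append(_analytic_step_truth(gt, ic, foot))
        k += 1

    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    left_bw = gt.foot_force_bw(t, "left")
    right_bw = gt.foot_force_bw(t, "right")
    if include_stomp:
        stomp = (t >= STOMP_TIME_S) & (t < STOMP_TIME_S + STOMP_DURATION_S)
        left_bw = left_bw + 0.3 * stomp
        right_bw = right_bw + 0.3 * stomp
    bw = profile.body_weight
    left = left_bw * bw
    right = right_bw * bw
    if profile.force_noise_n > 0:
        rng = np.random.default_rng(seed)
        left = np.clip(left + rng.normal(0, profile.force_noise_n, n), 0, None)
        right = np.clip(right + rng.normal(0, profile.force_noise_n, n), 0, None)
    rec = ForceRecording(
        time=t, force_left=left, force_right=right, rate=rate, body_weight=bw
    )
    return rec, gt


def simulate_imu(
    force_truth: GroundTruth,
    profile: RunnerProfile,
    rate: float = 200.0,
    seed: int = 0,
) -> dict[str, ImuRecording]:
    """Forward model: three 6-axis IMU streams consistent with the force truth.

    Sacrum vertical channel is (summed BW force - 1) * g before noise.
    Foot sensors carry a decaying-oscillation impact transient at each
    ipsilateral initial contact, a stride-frequency swing signature, and
    a sagittal gyro dip centered on initial contact.
    """
    rng = np.random.default_rng(seed)
    n = int(round(force_truth.duration_s * rate))
    t = np.arange(n) / rate
    stride_hz = 1.0 / (2.0 * force_truth.step_period_s)

    recordings = {}
    f_sum = force_truth.force_bw_at(t)
    stomp_pulse = np.zeros(n)
    if force_truth.stomp_time_s is not None:
        stomp_pulse = 50.0 * np.exp(
            -0.5 * ((t - force_truth.stomp_time_s) / 0.005) ** 2
        )

    # sacrum: vertical channel affine in summed force, plus smooth low-freq noise
    az = (f_sum - 1.0) * GRAVITY
    smooth = 0.05 * GRAVITY * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    accel = np.column_stack(
        [
            0.2 * np.sin(2 * np.pi * stride_hz * t) + stomp_pulse,
            0.2 * np.cos(2 * np.pi * stride_hz * t),
            az + smooth + stomp_pulse,
        ]
    )
    gyro = np.column_stack(
        [
            0.3 * np.sin(2 * np.pi * stride_hz * t),
            0.3 * np.cos(2 * np.pi * stride_hz * t),
            np.zeros(n),
        ]
    )
    recordings["sacrum"] = _finish_imu("sacrum", t, accel, gyro, profile, rate, rng)

    for site, foot in (("left_foot", "left"), ("right_foot", "right")):
        phase = 0.0 if foot == "left" else np.pi
        ax = 3.0 * np.sin(2 * np.pi * stride_hz * t + phase)
        ay = 1.0 * np.cos(2 * np.pi * stride_hz * t + phase)
        az_f = 2.0 * np.sin(4 * np.pi * stride_hz * t + phase)
        gy = 3.0 * np.sin(2 * np.pi * stride_hz * t + phase)
        ics = [s.ic_s for s in force_truth.steps if s.foot == foot]
        for ic in ics:
            rel = t - ic
            window = (rel >= 0) & (rel < 0.12)
            az_f = az_f + np.where(
                window,
                60.0 * np.exp(-np.clip(rel, 0, None) / 0.02)
                * np.sin(2 * np.pi * 30.0 * rel),
                0.0,
            )
            gy = gy - 6.0 * np.exp(-0.5 * (rel / 0.015) ** 2)
        accel = np.column_stack([ax + stomp_pulse, ay, az_f + stomp_pulse])
        gyro = np.column_stack([np.zeros(n), gy, np.zeros(n)])
        recordings[site] = _finish_imu(site, t, accel, gyro, profile, rate, rng)
    return recordings


def _finish_imu(site, t, accel, gyro, profile, rate, rng) -> ImuRecording:
    if profile.imu_noise_ms2 > 0:
        accel = accel + rng.normal(0, profile.imu_noise_ms2, accel.shape)
    if profile.gyro_noise_rads > 0:
        gyro = gyro + rng.normal(0, profile.gyro_noise_rads, gyro.shape)
    accel = np.clip(accel, -ACCEL_CLIP_MS2, ACCEL_CLIP_MS2)
    return ImuRecording(site=site, time=t.copy(), accel=accel, gyro=gyro, rate=rate)


def inject_drift(recording, drift_ppm: float):
    """Scale a recording's timestamps by (1 + ppm * 1e-6); data untouched."""
    if not -200 <= drift_ppm <= 200:
        raise ContractError("drift_ppm must be within [-200, 200]")
    factor = 1.0 + drift_ppm * 1e-6
    return dataclasses.replace(recording, time=recording.time * factor)


def write_ground_truth_csv(trial_id: str, gt: GroundTruth, path) -> None:
    rows = [
        {
            "trial_id": trial_id,
            "step": k,
            "ic_s": s.ic_s,
            "to_s": s.to_s,
            "contact_time_s": s.contact_time_s,
            "stance_avg_bw": s.stance_average_bw,
            "peak_bw": s.peak_bw,
            "impulse_bws": s.impulse_bw_s,
            "loading_rate_bws": s.loading_rate_bw_s,
        }
        for k, s in enumerate(gt.steps)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def simulate_cohort(
    n_participants: int,
    paces: int | list[float],
    duration_s: float,
    seed: int,
    out_dir,
    noise: bool = False,
) -> list[Path]:
    """Write a full synthetic cohort; returns per-participant manifest paths.

    ``paces`` is either a count (velocities drawn per participant from the
    2.33-5.36 m/s working range) or an explicit velocity list shared by
    everyone.  Same seed, same files, byte for byte.
    """
    if n_participants < 2:
        raise ContractError("cohort needs at least 2 participants")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest_paths = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        mass = float(rng.uniform(54, 82))
        if isinstance(paces, int):
            v0 = float(rng.uniform(2.4, 5.36 - 0.3 * (paces - 1)))
            velocities = [v0 + 0.3 * k for k in range(paces)]
        else:
            velocities = [float(v) for v in paces]
        profile = RunnerProfile(
            participant_id=pid,
            mass_kg=mass,
            impact_amplitude_bw=0.15 if noise else 0.0,
            force_noise_n=2.0 if noise else 0.0,
            imu_noise_ms2=0.2 if noise else 0.0,
            gyro_noise_rads=0.02 if noise else 0.0,
            drift_ppm=float(rng.uniform(-60, 60)),
        )
        trials = []
        for k, v in enumerate(velocities):
            trial_id = f"{pid}_T{k + 1}"
            trial_seed = int(rng.integers(0, 2**31 - 1))
            force, gt = simulate_force(
                profile, v, duration_s, seed=trial_seed, include_stomp=True
            )
            imus = simulate_imu(gt, profile, seed=trial_seed)
            force = inject_drift(force, profile.drift_ppm)

            force_path = f"{trial_id}_force.csv"
            write_force_csv(force, out_dir / force_path)
            imu_paths = {}
            for site, suffix in (
                ("left_foot", "lfoot"),
                ("right_foot", "rfoot"),
                ("sacrum", "sacrum"),
            ):
                p_rel = f"{trial_id}_{suffix}.csv"
                write_imu_csv(imus[site], out_dir / p_rel)
                imu_paths[site] = p_rel
            write_ground_truth_csv(trial_id, gt, out_dir / f"{trial_id}_truth.csv")
            trials.append(
                TrialSpec(
                    trial_id=trial_id,
                    pace_label=f"pace{k + 1}",
                    target_velocity=v,
                    imu_paths=imu_paths,
                    force_path=force_path,
                )
            )
        manifest = TrialManifest(
            participant_id=pid, mass_kg=mass, trials=trials, seed=seed
        )
        mpath = out_dir / f"{pid}_manifest.yaml"
        write_manifest(manifest, mpath)
        manifest_paths.append(mpath)
    index = out_dir / "cohort.yaml"
    import yaml

    with open(index, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"seed": seed, "manifests": [p.name for p in manifest_paths]},
            fh,
            sort_keys=False,
        )
    return manifest_paths
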