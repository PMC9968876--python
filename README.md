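# imugrf

Estimate vertical ground reaction force (GRF) waveforms during running
from three body-worn inertial measurement units (two feet + sacrum),
using a sequence-to-sequence LSTM, and evaluate agreement against
force-sensing-insole measurements.

The package implements the full pipeline:

1. **I/O** (`imugrf.io_store`) — CSV readers/writers for IMU streams
   (200 Hz, 6 channels), bilateral insole forces (100 Hz), YAML trial
   manifests, and estimate/summary tables.
2. **Signal processing** (`imugrf.sigproc`) — downsampling to the
   100 Hz working rate and zero-lag Butterworth low-pass filtering
   (4th order / 35 Hz for inertial channels, 2nd order / 20 Hz for
   force).
3. **Synchronization** (`imugrf.sync_align`) — foot-stomp offset
   detection and iterative clock-drift correction that inserts/removes
   zero samples in swing phases until every paired initial contact
   matches within ±0.02 s (stance samples are never touched).
4. **Windowing** (`imugrf.windowing`) — assembly of the 24-channel
   input (3 sensors × 6 raw channels + per-sensor acceleration and
   angular-velocity magnitudes) and tiling into non-overlapping 4 s
   windows (400 samples × 24 in, 400 × 1 out, body-weight units).
5. **Model** (`imugrf.seq2seq_model`) — a single-layer unidirectional
   LSTM with per-timestep linear readout, trained with Adam on MSE
   over all 400 output steps. Implemented in pure numpy (deterministic
   under a fixed seed), with grouped 70/15/15 hyperparameter search and
   leave-one-participant-out cross-validation (LOOCV).
6. **Kinetics** (`imugrf.gait_kinetics`) — estimate post-processing
   (filter, 5% BW zeroing, <0.050 s contact removal), initial-contact /
   toe-off detection at the 5% BW threshold, and contact time, stance
   average, impulse, peak force and average loading rate.
7. **Agreement** (`imugrf.agreement_eval`) — stance/waveform RMSE,
   Pearson r² with strength bands, OLS regression with 95% CIs,
   Bland-Altman bias and limits of agreement, per-velocity tables.
8. **Simulator** (`imugrf.synthetic_runner`) — a ground-truth-annotated
   synthetic runner (half-sine stance force satisfying the
   impulse-momentum constraint, velocity-dependent contact time and
   step frequency, optional impact bump, sensor noise, clock drift)
   so the entire pipeline is testable without recorded data.

## CLI

```sh
# synthetic cohort: 15 participants x 5 paces
imugrf simulate --participants 15 --paces 5 --duration 60 --seed 7 --out data/

# preprocess (resample, filter, sync, drift-correct) every trial
imugrf preprocess --cohort data/ --out work/

# LOOCV estimation + agreement tables
imugrf loocv --cohort data/ --hidden-units 42 --epochs 60 --seed 7 --out results/

# train a single model on all trials
imugrf train --cohort data/ --out model/

# recompute agreement statistics from saved estimates
imugrf evaluate --estimates results/ --out eval/
```

Exit codes: 0 success, 2 usage error, 3 data/contract error.

## Layout

```
src/imugrf/        package modules (one per pipeline stage)
tests/             pytest suite; tests/test_acceptance.py holds the
                   acceptance criteria, including a slow end-to-end
                   LOOCV parameter-recovery run (marked "slow")
scripts/acceptance.py
```
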