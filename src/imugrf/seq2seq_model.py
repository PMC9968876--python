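"""Sequence-to-sequence LSTM regression from inertial windows to GRF.

A single-layer unidirectional LSTM with a per-timestep linear read-out,
trained with mean squared error over all 400 output steps using Adam
(gradient decay / squared-gradient decay / L2 penalty as configuration).
The network, backpropagation through time and the optimizer are
implemented in numpy: training problems in this package are small
(tens of hidden units, a few hundred windows) and the implementation is
fully deterministic under a fixed seed.

Gate convention (standard formulation):

    i = sigmoid(x Wx_i + h Wh_i + b_i)      input gate
    f = sigmoid(x Wx_f + h Wh_f + b_f)      forget gate (bias init +1)
    g = tanh   (x Wx_g + h Wh_g + b_g)      candidate
    o = sigmoid(x Wx_o + h Wh_o + b_o)      output gate
    c' = f * c + i * g ;  h' = o * tanh(c') ;  y = h' Wy + by
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ContractError, TrainingError
from .windowing import (
    N_CHANNELS,
    WINDOW_SAMPLES,
    WindowPair,
    concatenate_estimates,
    make_windows,
)


@dataclass(frozen=True)
class ModelConfig:
    hidden_units: int = 42
    learning_rate: float = 1e-3
    #: per-epoch multiplicative learning-rate decay (1.0 = constant)
    learning_rate_decay: float = 1.0
    l2_penalty: float = 1e-4
    gradient_decay: float = 0.9
    squared_gradient_decay: float = 0.999
    max_epochs: int = 60
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ContractError("hidden_units must be positive")
        if not (0 < self.learning_rate):
            raise ContractError("learning_rate must be positive")


@dataclass(frozen=True)
class SplitPlan:
    """Participant-grouped train/validation/test fractions."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ContractError("split fractions must sum to 1")


@dataclass
class TrialData:
    """One preprocessed trial ready for windowing."""

    trial_id: str
    participant_id: str
    channels: np.ndarray  # (T, 24)
    force_bw: np.ndarray  # (T,)
    velocity: float = float("nan")


def _init_params(n_in: int, n_hidden: int, rng: np.random.Generator) -> dict:
    def glorot(shape):
        lim = math.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)

    h = n_hidden
    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0  # forget-gate bias
    return {
        "Wx": glorot((n_in, 4 * h)),
        "Wh": glorot((h, 4 * h)),
        "b": b,
        "Wy": glorot((h, 1)),
        "by": np.zeros(1),
    }


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _forward(params: dict, x: np.ndarray, want_cache: bool):
    """x: (B, T, D) -> y: (B, T, 1); cache holds per-step activations."""
    B, T, _ = x.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    ys = np.empty((B, T, 1))
    cache = [] if want_cache else None
    xw = x @ params["Wx"]  # (B, T, 4H), hoisted out of the loop
    for t in range(T):
        z = xw[:, t] + h @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        ys[:, t] = h_new @ params["Wy"] + params["by"]
        if want_cache:
            cache.append((i, f, g, o, c, tc, h))
        h, c = h_new, c_new
    return ys, cache


def _backward(params: dict, x: np.ndarray, cache, dys: np.ndarray) -> dict:
    """BPTT for the MSE-gradient dys (B, T, 1)."""
    B, T, _ = x.shape
    H = params["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = cache[t]
        h_t = o * tc
        dy = dys[:, t]
        grads["Wy"] += h_t.T @ dy
        grads["by"] += dy.sum(axis=0)
        dh = dy @ params["Wy"].T + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["Wx"] += x[:, t].T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh_next = dz @ params["Wh"].T
    return grads


@dataclass
class TrainedModel:
    """LSTM parameters plus the normalization statistics learned with them."""

    params: dict
    norm_mean: np.ndarray
    norm_std: np.ndarray
    config: ModelConfig
    channel_names: tuple
    loss_trace: list = field(default_factory=list)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean) / self.norm_std


def train(pairs: list[WindowPair], config: ModelConfig) -> TrainedModel:
    """Train on a list of windows; deterministic given ``config.seed``."""
    if not pairs:
        raise ContractError("need at least one training window")
    x = np.stack([p.x for p in pairs])  # (N, T, D)
    y = np.stack([p.y.reshape(-1, 1) for p in pairs])  # (N, T, 1)
    mean = x.reshape(-1, x.shape[-1]).mean(axis=0)
    std = x.reshape(-1, x.shape[-1]).std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    xn = (x - mean) / std

    rng = np.random.default_rng(config.seed)
    params = _init_params(x.shape[-1], config.hidden_units, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    b1, b2 = config.gradient_decay, config.squared_gradient_decay
    eps = 1e-8
    step = 0
    n = len(pairs)
    batch = min(config.batch_size, n)
    trace = []
    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.learning_rate_decay**epoch
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, batch):
            idx = order[lo : lo + batch]
            xb, yb = xn[idx], y[idx]
            ys, cache = _forward(params, xb, want_cache=True)
            err = ys - yb
            loss = float(np.mean(err * err))
            if not np.isfinite(loss):
                raise TrainingError(f"loss became non-finite at epoch {epoch}")
            epoch_loss += loss * len(idx)
            dys = (2.0 / err.size) * err
            grads = _backward(params, xb, cache, dys)
            step += 1
            for k in params:
                gk = grads[k]
                if config.l2_penalty and k in ("Wx", "Wh", "Wy"):
                    gk = gk + config.l2_penalty * params[k]
                m[k] = b1 * m[k] + (1 - b1) * gk
                v[k] = b2 * v[k] + (1 - b2) * gk * gk
                mhat = m[k] / (1 - b1**step)
                vhat = v[k] / (1 - b2**step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        trace.append(epoch_loss / n)
    return TrainedModel(
        params=params,
        norm_mean=mean,
        norm_std=std,
        config=config,
        channel_names=tuple(f"ch{i}" for i in range(x.shape[-1])),
        loss_trace=trace,
    )


def estimate(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Map one 400 x 24 window to a 400 x 1 GRF estimate (no post-processing)."""
    x = np.asarray(x, float)
    if x.shape != (WINDOW_SAMPLES, N_CHANNELS):
        raise ContractError(
            f"expected a {WINDOW_SAMPLES}x{N_CHANNELS} window, got {x.shape}"
        )
    xn = model.normalize(x)[None]
    ys, _ = _forward(model.params, xn, want_cache=False)
    return ys[0]


def estimate_batch(model: TrainedModel, xs: np.ndarray) -> np.ndarray:
    """Vectorized inference over a stack of windows (N, 400, 24)."""
    xn = model.normalize(np.asarray(xs, float))
    ys, _ = _forward(model.params, xn, want_cache=False)
    return ys


def _split_participants(
    participants: list[str], plan: SplitPlan, rng: np.random.Generator
):
    parts = sorted(set(participants))
    if len(parts) < 3:
        raise ContractError("need >= 3 participants for a grouped 70/15/15 split")
    order = list(rng.permutation(parts))
    n = len(order)
    n_val = max(1, int(round(plan.val_frac * n)))
    n_test = max(1, int(round(plan.test_frac * n)))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ContractError("too few participants to populate all three splits")
    return (
        set(order[:n_train]),
        set(order[n_train : n_train + n_val]),
        set(order[n_train + n_val :]),
    )


def _windows_for(trials: list[TrialData], participants) -> list[WindowPair]:
    out = []
    for t in trials:
        if t.participant_id in participants:
            out.extend(make_windows(t.channels, t.force_bw, trial_id=t.trial_id))
    return out


def _rmse_on(model: TrainedModel, pairs: list[WindowPair]) -> float:
    xs = np.stack([p.x for p in pairs])
    ys = np.stack([p.y.reshape(-1, 1) for p in pairs])
    est = estimate_batch(model, xs)
    return float(np.sqrt(np.mean((est - ys) ** 2)))


def optimize_hyperparameters(
    trials: list[TrialData],
    search_space: dict,
    plan: SplitPlan,
    budget: int,
    seed: int = 0,
    base_config: ModelConfig = ModelConfig(),
) -> tuple[ModelConfig, list[dict]]:
    """Select the configuration with the lowest validation RMSE.

    ``search_space`` maps ModelConfig field names to candidate values.
    The full grid is enumerated when it fits the budget, otherwise a
    seeded random subset is evaluated.  A degenerate one-point space is
    returned unevaluated (flagged in the trace).
    """
    keys = sorted(search_space)
    grid = [
        dict(zip(keys, combo))
        for combo in itertools.product(*[search_space[k] for k in keys])
    ]
    if len(grid) == 1:
        cfg = replace(base_config, **grid[0])
        return cfg, [{"config": cfg, "evaluated": False}]
    if budget < 2:
        raise ContractError("hyperparameter search needs a budget of >= 2")

    rng = np.random.default_rng(seed)
    train_p, val_p, test_p = _split_participants(
        [t.participant_id for t in trials], plan, rng
    )
    train_pairs = _windows_for(trials, train_p)
    val_pairs = _windows_for(trials, val_p)
    test_pairs = _windows_for(trials, test_p)
    if not (train_pairs and val_pairs and test_pairs):
        raise ContractError("a split partition produced no windows")

    if len(grid) > budget:
        pick = rng.choice(len(grid), size=budget, replace=False)
        grid = [grid[int(i)] for i in sorted(pick)]

    trace = []
    best = None
    for point in grid:
        cfg = replace(base_config, **point)
        model = train(train_pairs, cfg)
        val_rmse = _rmse_on(model, val_pairs)
        test_rmse = _rmse_on(model, test_pairs)
        trace.append(
            {
                "config": cfg,
                "evaluated": True,
                "val_rmse": val_rmse,
                "test_rmse": test_rmse,
            }
        )
        if best is None or val_rmse < best[0]:
            best = (val_rmse, cfg)
    return best[1], trace


def loocv(
    trials: list[TrialData],
    config: ModelConfig,
    return_models: bool = False,
):
    """Leave-one-participant-out estimates, concatenated per trial.

    For each participant a model is trained on every other participant's
    windows; the held-out participant's trials are estimated window by
    window and reassembled to trial length (uncovered tails zero-filled).
    With ``return_models`` the per-fold TrainedModel objects are returned
    alongside the estimates (fold key = held-out participant).
    """
    participants = sorted({t.participant_id for t in trials})
    if len(participants) < 2:
        raise ContractError("LOOCV needs at least 2 participants")
    estimates: dict[str, np.ndarray] = {}
    models: dict[str, TrainedModel] = {}
    for held_out in participants:
        train_pairs = _windows_for(
            trials, {p for p in participants if p != held_out}
        )
        model = train(train_pairs, config)
        models[held_out] = model
        for t in trials:
            if t.participant_id != held_out:
                continue
            wins = make_windows(t.channels, t.force_bw, trial_id=t.trial_id)
            if not wins:
                estimates[t.trial_id] = np.zeros(len(t.force_bw))
                continue
            ys = estimate_batch(model, np.stack([w.x for w in wins]))
            outputs = [
                (w.start_index, ys[k].reshape(-1)) for k, w in enumerate(wins)
            ]
            estimates[t.trial_id] = concatenate_estimates(
                outputs, len(t.force_bw)
            )
    if return_models:
        return estimates, models
    return estimates
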