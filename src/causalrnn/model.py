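"""Leaky tanh recurrent network for the causal-judgment task.

The continuous-time dynamics  tau dx/dt = -x + tanh(W x + B u)  are integrated
with forward Euler at step dt, giving the discrete update

    x[t+1] = (1 - alpha) x[t] + alpha * tanh(W x[t] + B u[t+1]),   alpha = dt / tau.

The scalar judgment is y[t] = sigmoid(C x[t]); a trial is judged "true" when
the mean output over the final window of timesteps exceeds 0.5.  Training
minimizes binary cross-entropy over that window with gradients obtained by
backpropagation through time (written out explicitly in numpy) and an Adam
optimizer.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .dag import CausalDag, enumerate_dags, categorize_dag
from .task import TaskConfig, TrialBatch, all_queries, generate_batch


@dataclass
class RnnParams:
    """Weights and time constants of the leaky tanh RNN."""

    W: np.ndarray  # J x J recurrent
    B: np.ndarray  # J x M input
    C: np.ndarray  # J output (read out as C . x)
    tau: float = 5.0
    dt: float = 1.0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float).reshape(-1)
        j = self.W.shape[0]
        if self.W.shape != (j, j) or self.B.shape[0] != j or self.C.shape[0] != j:
            raise ValueError("inconsistent weight shapes")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha = dt/tau must lie in (0, 1]")

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]


@dataclass
class TrajectoryRecord:
    states: np.ndarray  # T x J
    outputs: np.ndarray  # T


@dataclass
class TrainConfig:
    n_hidden: int = 128
    alpha: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    n_steps: int = 8_000
    seed: int = 0
    loss_window: float = 1.0     # fraction of timesteps carrying the BCE loss
    decision_window: float = 0.1  # trailing fraction used to read out decisions
    eval_every: int = 250
    eval_trials: int = 800
    target_accuracy: float = 0.95
    grad_clip: float = 1.0
    w_init_gain: float = 1.5  # scales the Glorot std of W (recurrent memory)
    b_init_gain: float = 3.0  # scales the Glorot std of B (input drive)
    l2_weight: float = 1e-4   # L2 penalty on W, B, C
    l2_activity: float = 5e-3  # L2 penalty on mean squared hidden activity

    def __post_init__(self):
        if min(self.n_hidden, self.learning_rate, self.batch_size, self.n_steps) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if not (0.0 < self.loss_window <= 1.0 and 0.0 < self.decision_window <= 1.0):
            raise ValueError("loss/decision windows must be fractions in (0, 1]")


def init_params(train_cfg: TrainConfig, n_inputs: int, rng) -> RnnParams:
    """Glorot-scaled W and B, zero-initialized readout C."""
    j = train_cfg.n_hidden
    w = rng.normal(0.0, train_cfg.w_init_gain * np.sqrt(1.0 / j), size=(j, j))
    b = rng.normal(
        0.0, train_cfg.b_init_gain * np.sqrt(2.0 / (j + n_inputs)), size=(j, n_inputs)
    )
    c = np.zeros(j)
    return RnnParams(W=w, B=b, C=c, tau=1.0 / train_cfg.alpha, dt=1.0)


def step(x: np.ndarray, u: np.ndarray, params: RnnParams) -> np.ndarray:
    """One Euler update; broadcasts over leading batch dimensions."""
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(u))):
        raise FloatingPointError("non-finite state or input")
    a = params.alpha
    return (1.0 - a) * x + a * np.tanh(x @ params.W.T + u @ params.B.T)


def simulate(
    params: RnnParams, inputs: np.ndarray, x0: Optional[np.ndarray] = None
) -> TrajectoryRecord:
    """Iterate the update over the rows of a T x M input matrix from x0 (default 0)."""
    t_total = inputs.shape[0]
    x = np.zeros(params.n_hidden) if x0 is None else np.asarray(x0, dtype=float)
    states = np.empty((t_total, params.n_hidden))
    for t in range(t_total):
        x = step(x, inputs[t], params)
        states[t] = x
    return TrajectoryRecord(states=states, outputs=expit(states @ params.C))


def simulate_batch(
    params: RnnParams, inputs: np.ndarray, x0: Optional[np.ndarray] = None
) -> np.ndarray:
    """Batched forward pass; returns states of shape (n, T, J)."""
    n, t_total, _ = inputs.shape
    a = params.alpha
    x = np.zeros((n, params.n_hidden)) if x0 is None else np.broadcast_to(
        x0, (n, params.n_hidden)
    ).copy()
    states = np.empty((n, t_total, params.n_hidden))
    wt, bt = params.W.T, params.B.T
    for t in range(t_total):
        x = (1.0 - a) * x + a * np.tanh(x @ wt + inputs[:, t] @ bt)
        states[:, t] = x
    return states


def decision(traj: TrajectoryRecord, window: float = 0.1) -> bool:
    """True iff the mean output over the final window fraction exceeds 0.5."""
    if not (0.0 < window <= 1.0):
        raise ValueError("window must be in (0, 1]")
    n = max(1, int(round(window * len(traj.outputs))))
    return bool(traj.outputs[-n:].mean() > 0.5)


def batch_decisions(params: RnnParams, inputs: np.ndarray, window: float = 0.1) -> np.ndarray:
    states = simulate_batch(params, inputs)
    n_win = max(1, int(round(window * inputs.shape[1])))
    outputs = expit(states[:, -n_win:] @ params.C)
    return outputs.mean(axis=1) > 0.5


def _loss_and_grads(params: RnnParams, inputs: np.ndarray, labels: np.ndarray,
                    window: float, l2_activity: float = 0.0):
    """BCE over the final window plus gradients via backprop through time.

    Forward:  a_t = W x_{t-1} + B u_t;  x_t = (1-alpha) x_{t-1} + alpha tanh(a_t).
    The tanh values are cached so the backward pass reuses 1 - tanh^2.
    The pass runs in float32 (the optimizer accumulates in float64); gradient
    agreement with finite differences is tested at the float32 noise floor.
    """
    f32 = np.float32
    n, t_total, _ = inputs.shape
    j = params.n_hidden
    a = f32(params.alpha)
    w32 = params.W.astype(f32)
    b32 = params.B.astype(f32)
    c32 = params.C.astype(f32)
    u32 = np.ascontiguousarray(inputs, dtype=f32)
    wt, bt = w32.T, b32.T

    xs = np.zeros((t_total + 1, n, j), dtype=f32)
    th = np.empty((t_total, n, j), dtype=f32)
    for t in range(t_total):
        th[t] = np.tanh(xs[t] @ wt + u32[:, t] @ bt)
        xs[t + 1] = (1.0 - a) * xs[t] + a * th[t]

    n_win = max(1, int(round(window * t_total)))
    y = expit((xs[1:] @ c32).astype(np.float64))  # (T, n)
    target = labels.astype(float)
    win = slice(t_total - n_win, t_total)
    eps = 1e-12
    loss = -np.mean(
        target * np.log(y[win] + eps) + (1.0 - target) * np.log(1.0 - y[win] + eps)
    )

    # d loss / d logit, nonzero only in the window
    dlogit = np.zeros((t_total, n), dtype=f32)
    dlogit[win] = (y[win] - target) / (n_win * n)

    dW = np.zeros((j, j), dtype=f32)
    dB = np.zeros_like(b32)
    dC = np.einsum("tn,tnj->j", dlogit, xs[1:])
    # firing-rate penalty: l2_activity * mean(x^2) over (T, n, j)
    act_coef = f32(2.0 * l2_activity / (t_total * n * j))
    if l2_activity:
        loss += l2_activity * float(np.mean(xs[1:].astype(np.float64) ** 2))
    g = np.zeros((n, j), dtype=f32)  # d loss / d x_t, accumulated backwards
    for t in range(t_total - 1, -1, -1):
        g = g + dlogit[t][:, None] * c32
        if l2_activity:
            g = g + act_coef * xs[t + 1]
        h = a * (1.0 - th[t] ** 2) * g  # back through the tanh branch
        dW += h.T @ xs[t]
        dB += h.T @ u32[:, t]
        g = (1.0 - a) * g + h @ w32
    return loss, dW.astype(np.float64), dB.astype(np.float64), dC.astype(np.float64)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def update(self, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _cosine_lr(
    base: float, step: int, total: int,
    floor_frac: float = 0.1, hold_frac: float = 0.5,
) -> float:
    """Hold the base rate for the first hold_frac of the run, then cosine-decay
    to floor_frac*base.  The hold phase preserves the exploration needed to
    escape the initial chance plateau; the decay tames late oscillations."""
    hold = hold_frac * total
    if step <= hold:
        return base
    floor = floor_frac * base
    frac = (step - hold) / max(1.0, total - hold)
    return floor + 0.5 * (base - floor) * (1 + np.cos(np.pi * frac))


def evaluate_accuracy(
    params: RnnParams,
    task: TaskConfig,
    n_trials: int,
    seed,
    dag_filter=None,
    window: float = 0.1,
):
    """Judgment accuracy on freshly generated trials, with a per-(DAG, query) table.

    ``dag_filter`` restricts generation to a single CausalDag or to every DAG
    of a named 3-node category.  Returns (accuracy, DataFrame).
    """
    fixed = None
    if isinstance(dag_filter, CausalDag):
        fixed = [dag_filter]
    elif isinstance(dag_filter, str):
        fixed = [d for d in enumerate_dags(3) if categorize_dag(d) == dag_filter]
    if fixed is None:
        batch = generate_batch(task, n_trials, seed)
    else:
        # spread trials evenly over the filtered DAGs
        ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
        parts, sizes = [], np.full(len(fixed), n_trials // len(fixed))
        sizes[: n_trials % len(fixed)] += 1
        for dag, m, s in zip(fixed, sizes, ss.spawn(len(fixed))):
            if m > 0:
                parts.append(generate_batch(task, int(m), s, fixed_dag=dag))
        batch = TrialBatch(
            inputs=np.concatenate([p.inputs for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            queries=np.concatenate([p.queries for p in parts]),
            dag_indices=np.concatenate([p.dag_indices for p in parts]),
            observations=np.concatenate([p.observations for p in parts]),
        )
    correct = batch_decisions(params, batch.inputs, window) == batch.labels
    df = pd.DataFrame(
        {
            "dag_index": batch.dag_indices,
            "cause": batch.queries[:, 0],
            "effect": batch.queries[:, 1],
            "label": batch.labels,
            "correct": correct,
        }
    )
    table = (
        df.groupby(["dag_index", "cause", "effect"], as_index=False)
        .agg(n=("correct", "size"), accuracy=("correct", "mean"))
    )
    return float(correct.mean()), table


def train(
    task: TaskConfig,
    cfg: TrainConfig,
    progress: Optional[Callable[[dict], None]] = None,
):
    """Train an RNN on the causal-judgment task.

    Returns (RnnParams, history DataFrame with columns step/loss/holdout_accuracy).
    Held-out accuracy is measured on freshly generated trials every
    ``eval_every`` steps; training stops early once it reaches
    ``target_accuracy``.  Raises FloatingPointError if the loss diverges.
    """
    ss = np.random.SeedSequence(cfg.seed)
    init_ss, data_ss, eval_ss = ss.spawn(3)
    rng = np.random.default_rng(init_ss)
    params = init_params(cfg, task.n_inputs, rng)
    opt = _Adam(
        [params.W.shape, params.B.shape, params.C.shape], cfg.learning_rate
    )
    data_seeds = data_ss.spawn(cfg.n_steps)
    eval_seeds = eval_ss.spawn(cfg.n_steps // cfg.eval_every + 2)

    history = []
    t_start = time.time()
    for it in range(cfg.n_steps):
        batch = generate_batch(task, cfg.batch_size, data_seeds[it])
        loss, dW, dB, dC = _loss_and_grads(
            params, batch.inputs, batch.labels, cfg.loss_window, cfg.l2_activity
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at step {it}: loss={loss}")
        if cfg.l2_weight:
            dW += 2.0 * cfg.l2_weight * params.W
            dB += 2.0 * cfg.l2_weight * params.B
            dC += 2.0 * cfg.l2_weight * params.C
        gnorm = np.sqrt(sum(float((g * g).sum()) for g in (dW, dB, dC)))
        if cfg.grad_clip and gnorm > cfg.grad_clip:
            scale = cfg.grad_clip / gnorm
            dW, dB, dC = dW * scale, dB * scale, dC * scale
        upd = opt.update([dW, dB, dC],
                         lr=_cosine_lr(cfg.learning_rate, it, cfg.n_steps))
        params.W -= upd[0]
        params.B -= upd[1]
        params.C -= upd[2]

        if (it + 1) % cfg.eval_every == 0 or it == cfg.n_steps - 1:
            acc, _ = evaluate_accuracy(
                params, task, cfg.eval_trials,
                eval_seeds[(it + 1) // cfg.eval_every], window=cfg.decision_window,
            )
            rec = {
                "step": it + 1,
                "loss": float(loss),
                "holdout_accuracy": acc,
                "elapsed_s": time.time() - t_start,
            }
            history.append(rec)
            if progress is not None:
                progress(rec)
            if acc >= cfg.target_accuracy:
                break
    return params, pd.DataFrame(history)
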