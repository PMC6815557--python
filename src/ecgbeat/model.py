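"""An LSTM beat classifier trained with focal loss, implemented on numpy.

Architecture
------------
Each 250-sample beat is fed one sample per timestep through a single LSTM
layer; the final hidden vector is the beat representation and passes through
a ReLU fully-connected layer and a linear output layer, followed by softmax
over the eight beat classes.

Two cell variants are provided.  The default is the standard cell::

    f_t  = sigmoid(W_f · [a_{t-1}, x_t] + b_f)          (i_t, o_t likewise)
    c_in = tanh   (W_c · [a_{t-1}, x_t] + b_c)
    c_t  = f_t ⊙ c_{t-1} + i_t ⊙ c_in
    a_t  = o_t ⊙ tanh(c_t)

``standard_lstm=False`` selects a peephole-style variant that feeds the
*previous* cell state into all four gate pre-activations — the gates act on
``[a_{t-1}, x_t, c_{t-1}]`` (note the output gate then sees ``c_{t-1}``,
not ``c_t`` as in classic peephole cells).  The unbounded cell state
entering sigmoid gates makes this variant markedly slower to train; it is
kept for comparison, with gradients exact in both forms.

Loss
----
With ``p`` the predicted probability of the true class, cross-entropy is
``-log p`` and focal loss is ``-(1-p)^γ · log p`` (no class-balance term).
The modulating factor ``(1-p)^γ`` downweights confidently-classified easy
beats — overwhelmingly the majority normal class — so gradient mass shifts
toward hard minority-class beats without resampling the data.  ``γ=0``
recovers cross-entropy exactly.

Gradients are exact backpropagation through time over all timesteps
(including the cell-state pathways into every gate and the γ-modulated loss
factor); optimization uses Nadam (Adam with a Nesterov-style lookahead on
the first moment).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit as _sigmoid

from .dataset import BeatDataset

__all__ = [
    "LSTMParams",
    "LSTMState",
    "TrainConfig",
    "NadamState",
    "init_params",
    "lstm_step",
    "softmax",
    "forward",
    "cross_entropy",
    "focal_loss",
    "batch_loss",
    "backward",
    "nadam_update",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "write_history",
]

_PROB_FLOOR = 1e-12  # probability clamp before log, in both CE and FL


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference settings:
    64 LSTM cells, focal loss with γ=2, no dropout, 350 epochs, batch 128,
    Nadam at its usual defaults)."""

    epochs: int = 350
    batch_size: int = 128
    dropout: float = 0.0
    gamma: float = 2.0
    loss: str = "focal"  # "focal" | "cross_entropy"
    learning_rate: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0
    hidden_size: int = 64
    fc_width: int = 32
    n_classes: int = 8
    input_size: int = 1
    standard_lstm: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("focal", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


_GATE_NAMES = ("W_f", "W_i", "W_c", "W_o")
_ARRAY_NAMES = (
    "W_f", "W_i", "W_c", "W_o",
    "b_f", "b_i", "b_c", "b_o",
    "W_fc1", "b_fc1", "W_fc2", "b_fc2",
)


@dataclass
class LSTMParams:
    """All trainable parameters.

    Gate matrices have shape ``(H, 2H+D)`` in the peephole form (acting on
    ``[a_{t-1}, x_t, c_{t-1}]``) or ``(H, H+D)`` in the standard form.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    W_fc1: np.ndarray
    b_fc1: np.ndarray
    W_fc2: np.ndarray
    b_fc2: np.ndarray
    standard_lstm: bool = True

    @property
    def H(self) -> int:
        return self.W_f.shape[0]

    @property
    def D(self) -> int:
        w = self.W_f.shape[1]
        return w - self.H if self.standard_lstm else w - 2 * self.H

    def arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _ARRAY_NAMES}

    def copy(self) -> "LSTMParams":
        return LSTMParams(
            **{k: v.copy() for k, v in self.arrays().items()},
            standard_lstm=self.standard_lstm,
        )

    def zeros_like(self) -> "LSTMParams":
        return LSTMParams(
            **{k: np.zeros_like(v) for k, v in self.arrays().items()},
            standard_lstm=self.standard_lstm,
        )


@dataclass
class LSTMState:
    """Hidden/cell state after one step, with gate activations kept for
    diagnostics."""

    a: np.ndarray
    c: np.ndarray
    f: np.ndarray | None = None
    i: np.ndarray | None = None
    c_in: np.ndarray | None = None
    o: np.ndarray | None = None

    @classmethod
    def zero(cls, H: int) -> "LSTMState":
        return cls(a=np.zeros(H), c=np.zeros(H))


def init_params(
    H: int = 64,
    D: int = 1,
    H1: int = 32,
    C: int = 8,
    seed: int = 0,
    standard_lstm: bool = True,
) -> LSTMParams:
    """Glorot-uniform weights, zero biases except forget-gate bias = 1.

    The forget bias of 1 keeps the cell state initially persistent, the
    de-facto standard for trainable LSTMs.
    """
    for name, v in (("H", H), ("D", D), ("H1", H1), ("C", C)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    rng = np.random.default_rng(seed)
    in_w = (H + D) if standard_lstm else (2 * H + D)

    def glorot(n_out: int, n_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_out, n_in))

    return LSTMParams(
        W_f=glorot(H, in_w),
        W_i=glorot(H, in_w),
        W_c=glorot(H, in_w),
        W_o=glorot(H, in_w),
        b_f=np.ones(H),
        b_i=np.zeros(H),
        b_c=np.zeros(H),
        b_o=np.zeros(H),
        W_fc1=glorot(H1, H),
        b_fc1=np.zeros(H1),
        W_fc2=glorot(C, H1),
        b_fc2=np.zeros(C),
        standard_lstm=standard_lstm,
    )


def lstm_step(params: LSTMParams, x_t: np.ndarray, prev: LSTMState) -> LSTMState:
    """One cell update for a single example (diagnostic, non-batched)."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    if x_t.shape[0] != params.D:
        raise ValueError(f"x_t has length {x_t.shape[0]}, expected D={params.D}")
    if prev.a.shape[0] != params.H or prev.c.shape[0] != params.H:
        raise ValueError("previous state size does not match H")
    if params.standard_lstm:
        u = np.concatenate([prev.a, x_t])
    else:
        u = np.concatenate([prev.a, x_t, prev.c])
    f = _sigmoid(params.W_f @ u + params.b_f)
    i = _sigmoid(params.W_i @ u + params.b_i)
    c_in = np.tanh(params.W_c @ u + params.b_c)
    c = f * prev.c + i * c_in
    o = _sigmoid(params.W_o @ u + params.b_o)
    a = o * np.tanh(c)
    return LSTMState(a=a, c=c, f=f, i=i, c_in=c_in, o=o)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _stacked_weights(params: LSTMParams) -> tuple[np.ndarray, np.ndarray]:
    W = np.vstack([params.W_f, params.W_i, params.W_c, params.W_o])
    b = np.concatenate([params.b_f, params.b_i, params.b_c, params.b_o])
    return W, b


def _forward_batch(
    params: LSTMParams,
    X: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    train_mode: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the full network on a batch of beats.

    ``X`` has shape (B, T); each row is fed one sample per timestep
    (D=1).  Returns logits (B, C), probabilities (B, C) and the cache
    needed by :func:`backward`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B, T = X.shape
    H = params.H
    D = params.D
    if D != 1:
        raise ValueError("batched forward supports per-step input size D=1")
    W, b = _stacked_weights(params)
    a_hist = np.zeros((T + 1, B, H))
    c_hist = np.zeros((T + 1, B, H))
    f_h = np.empty((T, B, H))
    i_h = np.empty((T, B, H))
    cin_h = np.empty((T, B, H))
    o_h = np.empty((T, B, H))
    tanh_c = np.empty((T, B, H))
    peephole = not params.standard_lstm
    in_w = (2 * H + D) if peephole else (H + D)
    Wt = W.T.copy()
    U = np.empty((B, in_w))
    for t in range(T):
        U[:, :H] = a_hist[t]
        U[:, H] = X[:, t]
        if peephole:
            U[:, H + D :] = c_hist[t]
        G = U @ Wt
        G += b
        f = _sigmoid(G[:, :H])
        i = _sigmoid(G[:, H : 2 * H])
        c_in = np.tanh(G[:, 2 * H : 3 * H])
        o = _sigmoid(G[:, 3 * H :])
        c = f * c_hist[t] + i * c_in
        tc = np.tanh(c)
        a_hist[t + 1] = o * tc
        c_hist[t + 1] = c
        f_h[t], i_h[t], cin_h[t], o_h[t], tanh_c[t] = f, i, c_in, o, tc
    a_T = a_hist[T]
    if train_mode and dropout > 0.0:
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(a_T.shape) >= dropout) / (1.0 - dropout)
    else:
        mask = np.ones_like(a_T)
    a_drop = a_T * mask
    pre1 = a_drop @ params.W_fc1.T + params.b_fc1
    h1 = np.maximum(pre1, 0.0)
    z = h1 @ params.W_fc2.T + params.b_fc2
    yhat = softmax(z)
    cache = {
        "X": X,
        "a_hist": a_hist,
        "c_hist": c_hist,
        "f": f_h,
        "i": i_h,
        "c_in": cin_h,
        "o": o_h,
        "tanh_c": tanh_c,
        "mask": mask,
        "a_drop": a_drop,
        "h1": h1,
        "yhat": yhat,
    }
    return z, yhat, cache


def forward(
    params: LSTMParams,
    beat: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    train_mode: bool = False,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Network output for one beat: (logits, probabilities, cache)."""
    z, yhat, cache = _forward_batch(
        params, np.asarray(beat, dtype=float)[None, :], dropout, rng, train_mode
    )
    return z[0], yhat[0], cache


def cross_entropy(p_true: float | np.ndarray) -> float | np.ndarray:
    """``-log p`` on the true-class probability (clamped at 1e-12)."""
    p = np.clip(np.asarray(p_true, dtype=float), _PROB_FLOOR, 1.0)
    out = -np.log(p)
    return out.item() if out.ndim == 0 else out


def focal_loss(p_true: float | np.ndarray, gamma: float = 2.0) -> float | np.ndarray:
    """``-(1-p)^γ · log p``; γ=0 reduces exactly to cross-entropy."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    p = np.clip(np.asarray(p_true, dtype=float), _PROB_FLOOR, 1.0)
    out = -np.power(1.0 - p, gamma) * np.log(p)
    return out.item() if out.ndim == 0 else out


def batch_loss(
    yhat: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> float:
    """Mean per-example loss over a batch of probability rows."""
    yhat = np.atleast_2d(yhat)
    labels = np.atleast_1d(labels)
    if yhat.shape[0] == 0:
        raise ValueError("batch_loss on an empty batch")
    p = yhat[np.arange(yhat.shape[0]), labels]
    if config.loss == "focal":
        losses = focal_loss(p, config.gamma)
    else:
        losses = cross_entropy(p)
    return float(np.mean(losses))


def _loss_grad_wrt_logits(
    yhat: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> tuple[float, np.ndarray]:
    """Mean loss and its exact gradient with respect to the logits.

    With p the true-class probability, d loss/d p is ``-1/p`` for
    cross-entropy and ``γ(1-p)^(γ-1)·log p − (1-p)^γ/p`` for focal loss;
    the chain through softmax gives
    ``dz_j = (dL/dp) · p · (1[j=y] − ŷ_j)``.
    """
    B, _ = yhat.shape
    idx = np.arange(B)
    p = yhat[idx, labels]
    pc = np.clip(p, _PROB_FLOOR, 1.0)
    gamma = config.gamma if config.loss == "focal" else 0.0
    if gamma == 0.0:
        losses = -np.log(pc)
        dldp = -1.0 / pc
    else:
        one_m = 1.0 - p
        losses = -np.power(np.clip(one_m, 0.0, None), gamma) * np.log(pc)
        dldp = (
            gamma * np.power(np.clip(one_m, 1e-300, None), gamma - 1.0) * np.log(pc)
            - np.power(np.clip(one_m, 0.0, None), gamma) / pc
        )
    dz = yhat * (-(dldp * p))[:, None]
    dz[idx, labels] += dldp * p
    dz /= B
    return float(np.mean(losses)), dz


def backward(
    params: LSTMParams,
    X: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    cache: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, LSTMParams]:
    """Mean batch loss and its exact gradients via BPTT.

    Backpropagates through the fully-connected head, the dropout mask, and
    every timestep of the recurrence — including the cell-state pathways
    into all four gate pre-activations in the peephole form.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if cache is None:
        _, _, cache = _forward_batch(
            params, X, config.dropout, rng, train_mode=True
        )
    yhat = cache["yhat"]
    loss, dz = _loss_grad_wrt_logits(yhat, labels, config)

    grads = params.zeros_like()
    h1 = cache["h1"]
    a_drop = cache["a_drop"]
    grads.W_fc2[:] = dz.T @ h1
    grads.b_fc2[:] = dz.sum(axis=0)
    dh1 = dz @ params.W_fc2
    dh1[h1 <= 0.0] = 0.0
    grads.W_fc1[:] = dh1.T @ a_drop
    grads.b_fc1[:] = dh1.sum(axis=0)
    da = (dh1 @ params.W_fc1) * cache["mask"]

    H = params.H
    D = params.D
    T = X.shape[1]
    peephole = not params.standard_lstm
    W, _ = _stacked_weights(params)
    a_hist, c_hist = cache["a_hist"], cache["c_hist"]
    f_h, i_h, cin_h, o_h, tanh_c = (
        cache["f"], cache["i"], cache["c_in"], cache["o"], cache["tanh_c"]
    )
    dW = np.zeros_like(W)
    db = np.zeros(4 * H)
    dc = np.zeros_like(da)
    B = X.shape[0]
    in_w = (2 * H + D) if peephole else (H + D)
    dZ = np.empty((B, 4 * H))
    u = np.empty((B, in_w))
    for t in range(T - 1, -1, -1):
        f, i, c_in, o, tc = f_h[t], i_h[t], cin_h[t], o_h[t], tanh_c[t]
        c_prev = c_hist[t]
        do = da * tc
        dc = dc + da * o * (1.0 - tc * tc)
        dZ[:, :H] = (dc * c_prev) * f * (1.0 - f)
        dZ[:, H : 2 * H] = (dc * c_in) * i * (1.0 - i)
        dZ[:, 2 * H : 3 * H] = (dc * i) * (1.0 - c_in * c_in)
        dZ[:, 3 * H :] = do * o * (1.0 - o)
        dc_prev = dc * f
        u[:, :H] = a_hist[t]
        u[:, H] = X[:, t]
        if peephole:
            u[:, H + D :] = c_prev
        dW += dZ.T @ u
        db += dZ.sum(axis=0)
        du = dZ @ W
        da = du[:, :H]
        dc = dc_prev + (du[:, H + D :] if peephole else 0.0)
    grads.W_f[:], grads.W_i[:], grads.W_c[:], grads.W_o[:] = (
        dW[:H], dW[H : 2 * H], dW[2 * H : 3 * H], dW[3 * H :]
    )
    grads.b_f[:], grads.b_i[:], grads.b_c[:], grads.b_o[:] = (
        db[:H], db[H : 2 * H], db[2 * H : 3 * H], db[3 * H :]
    )
    return loss, grads


@dataclass
class NadamState:
    """First/second-moment accumulators per parameter array, plus step count."""

    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0

    @classmethod
    def zero(cls, params: LSTMParams) -> "NadamState":
        return cls(
            m={k: np.zeros_like(a) for k, a in params.arrays().items()},
            v={k: np.zeros_like(a) for k, a in params.arrays().items()},
        )


def nadam_update(
    params: LSTMParams,
    grads: LSTMParams,
    state: NadamState,
    config: TrainConfig,
) -> tuple[LSTMParams, NadamState]:
    """One Nadam step; pure (returns fresh params and state).

    Nadam applies Adam's bias-corrected moment estimates with a
    Nesterov-style lookahead on the first moment::

        m ← β1 m + (1-β1) g          v ← β2 v + (1-β2) g²
        m̂ = m/(1-β1^t)               v̂ = v/(1-β2^t)
        θ ← θ − lr · (β1 m̂ + (1-β1) g/(1-β1^t)) / (√v̂ + ε)
    """
    b1, b2, lr, eps = config.beta1, config.beta2, config.learning_rate, config.epsilon
    t = state.t + 1
    new_params = params.copy()
    new_m: dict[str, np.ndarray] = {}
    new_v: dict[str, np.ndarray] = {}
    bc1 = 1.0 - b1**t
    bc2 = 1.0 - b2**t
    p_arrays = new_params.arrays()
    g_arrays = grads.arrays()
    for name, g in g_arrays.items():
        m = b1 * state.m[name] + (1.0 - b1) * g
        v = b2 * state.v[name] + (1.0 - b2) * g * g
        m_hat = m / bc1
        v_hat = v / bc2
        lookahead = b1 * m_hat + (1.0 - b1) * g / bc1
        p_arrays[name] -= lr * lookahead / (np.sqrt(v_hat) + eps)
        new_m[name] = m
        new_v[name] = v
    return new_params, NadamState(m=new_m, v=new_v, t=t)


def _accuracy(yhat: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(np.argmax(yhat, axis=1) == labels))


def _eval_loss_acc(
    params: LSTMParams, X: np.ndarray, y: np.ndarray, config: TrainConfig,
    batch_size: int = 512,
) -> tuple[float, float]:
    losses, hits, total = 0.0, 0, 0
    for s in range(0, X.shape[0], batch_size):
        xb, yb = X[s : s + batch_size], y[s : s + batch_size]
        _, yhat, _ = _forward_batch(params, xb)
        losses += batch_loss(yhat, yb, config) * xb.shape[0]
        hits += int(np.sum(np.argmax(yhat, axis=1) == yb))
        total += xb.shape[0]
    return losses / total, hits / total


def train(
    train_ds: BeatDataset,
    val_ds: BeatDataset | None,
    config: TrainConfig,
    params: LSTMParams | None = None,
) -> tuple[LSTMParams, list[dict]]:
    """Mini-batch training loop.

    Each epoch: seeded shuffle, mini-batches of ``config.batch_size`` (last
    partial batch kept), forward → BPTT → Nadam.  Returns the trained
    parameters and a per-epoch history of train/val loss and accuracy.
    Deterministic given the config seed.  Raises ``RuntimeError`` if the
    loss stops being finite.
    """
    if train_ds.n == 0:
        raise ValueError("training set is empty")
    X = train_ds.matrix()
    y = train_ds.labels()
    Xv = val_ds.matrix() if val_ds is not None and val_ds.n else None
    yv = val_ds.labels() if Xv is not None else None
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(
            H=config.hidden_size,
            D=config.input_size,
            H1=config.fc_width,
            C=config.n_classes,
            seed=int(rng.integers(2**31 - 1)),
            standard_lstm=config.standard_lstm,
        )
    state = NadamState.zero(params)
    history: list[dict] = []
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            xb, yb = X[idx], y[idx]
            _, yhat, cache = _forward_batch(
                params, xb, config.dropout, rng, train_mode=True
            )
            loss, grads = backward(params, xb, yb, config, cache=cache)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            params, state = nadam_update(params, grads, state, config)
            ep_loss += loss * xb.shape[0]
            ep_hits += int(np.sum(np.argmax(yhat, axis=1) == yb))
        entry = {
            "epoch": epoch,
            "train_loss": ep_loss / n,
            "train_acc": ep_hits / n,
        }
        if Xv is not None:
            vl, va = _eval_loss_acc(params, Xv, yv, config)
            entry["val_loss"], entry["val_acc"] = vl, va
        else:
            entry["val_loss"], entry["val_acc"] = float("nan"), float("nan")
        history.append(entry)
    return params, history


def predict(
    params: LSTMParams,
    beats: BeatDataset | np.ndarray,
    batch_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (argmax, ties to the lowest index) and probability
    matrix; dropout disabled.  Invariant to how the input is batched."""
    X = beats.matrix() if isinstance(beats, BeatDataset) else np.atleast_2d(beats)
    probs = np.empty((X.shape[0], params.b_fc2.shape[0]))
    for s in range(0, X.shape[0], batch_size):
        _, yhat, _ = _forward_batch(params, X[s : s + batch_size])
        probs[s : s + batch_size] = yhat
    return np.argmax(probs, axis=1), probs


# ---------------------------------------------------------------------------
# Checkpoints and history files
# ---------------------------------------------------------------------------


def save_checkpoint(path: str | Path, params: LSTMParams, config: TrainConfig) -> Path:
    """Archive of named arrays plus a JSON config block (npz container)."""
    path = Path(path)
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(asdict(config)).encode(), dtype=np.uint8
        ),
        __standard_lstm__=np.array(int(params.standard_lstm)),
        **params.arrays(),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[LSTMParams, TrainConfig]:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        params = LSTMParams(
            **{name: data[name].copy() for name in _ARRAY_NAMES},
            standard_lstm=bool(int(data["__standard_lstm__"])),
        )
    known = {f.name for f in fields(TrainConfig)}
    return params, TrainConfig(**{k: v for k, v in cfg.items() if k in known})


def write_history(path: str | Path, history: Sequence[dict]) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("epoch,train_loss,train_acc,val_loss,val_acc\n")
        for h in history:
            fh.write(
                f"{h['epoch']},{h['train_loss']:.10g},{h['train_acc']:.10g},"
                f"{h['val_loss']:.10g},{h['val_acc']:.10g}\n"
            )
    return path
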