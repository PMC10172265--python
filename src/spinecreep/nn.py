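"""Gated recurrent network primitives in numpy.

Implements the LSTM cell used by the surrogate — input, forget and output
gates with sigmoid activation, a tanh candidate, cell-state update
``c = g_f ⊙ c_prev + g_i ⊙ c̄`` and hidden state ``h = g_o ⊙ tanh(c)`` (the
cell's output equals its hidden state) — together with batched forward and
backward-through-time passes, a per-timestep linear dense head, the masked
mean-squared-error loss (per-sequence mean over real steps of the squared
error norm, then mean over sequences) and an Adam optimizer.

Everything is plain float64 numpy; gradients are exact analytic BPTT and are
verified against numeric differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LSTMCellSpec",
    "LSTMState",
    "lstm_cell_step",
    "LSTMLayer",
    "DenseLayer",
    "masked_mse",
    "masked_mse_grad",
    "Adam",
]

GATES = ("i", "f", "o", "c")


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


@dataclass(frozen=True)
class LSTMCellSpec:
    """Per-gate weights of one LSTM cell: W^α (n×l), V^α (n×n), B^α (n)."""

    W: dict
    V: dict
    B: dict

    def __post_init__(self) -> None:
        for alpha in GATES:
            if alpha not in self.W or alpha not in self.V or alpha not in self.B:
                raise ValueError(f"missing weights for gate {alpha!r}")
        n = self.B["i"].shape[0]
        l = self.W["i"].shape[1]
        for alpha in GATES:
            if self.W[alpha].shape != (n, l) or self.V[alpha].shape != (n, n) or self.B[alpha].shape != (n,):
                raise ValueError("inconsistent gate weight shapes")

    @property
    def n_units(self) -> int:
        return self.B["i"].shape[0]


@dataclass(frozen=True)
class LSTMState:
    """Working memory h and long-term cell memory c of one cell."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "LSTMState":
        return cls(np.zeros(n), np.zeros(n))


def lstm_cell_step(s, state: LSTMState, weights: LSTMCellSpec):
    """One forward step of the LSTM cell on a single input vector.

    Returns ``(t, new_state)`` where the output ``t`` equals the new hidden
    state.  This is the literal single-vector contract; the batched layer
    below must agree with it (checked in tests).
    """
    s = np.asarray(s, dtype=float)
    n = weights.n_units
    if s.shape != (weights.W["i"].shape[1],) or state.h.shape != (n,) or state.c.shape != (n,):
        raise ValueError("shape mismatch between input, state and weights")

    def affine(alpha):
        return weights.W[alpha] @ s + weights.V[alpha] @ state.h + weights.B[alpha]

    g_i = sigmoid(affine("i"))
    g_f = sigmoid(affine("f"))
    g_o = sigmoid(affine("o"))
    c_bar = np.tanh(affine("c"))
    c = g_f * state.c + g_i * c_bar
    h = g_o * np.tanh(c)
    return h, LSTMState(h=h, c=c)


class LSTMLayer:
    """Batched LSTM layer returning full sequences, with analytic BPTT.

    Weights are packed as ``W`` (l, 4n), ``V`` (n, 4n), ``b`` (4n) in gate
    order i, f, o, c.  Initialization is Glorot-uniform with a unit forget
    bias.
    """

    def __init__(self, n_input: int, n_units: int, rng: np.random.Generator):
        self.n_input = n_input
        self.n_units = n_units
        lim_w = np.sqrt(6.0 / (n_input + n_units))
        lim_v = np.sqrt(6.0 / (2 * n_units))
        self.W = rng.uniform(-lim_w, lim_w, (n_input, 4 * n_units))
        self.V = rng.uniform(-lim_v, lim_v, (n_units, 4 * n_units))
        self.b = np.zeros(4 * n_units)
        self.b[n_units:2 * n_units] = 1.0  # forget-gate bias

    @property
    def params(self):
        return [self.W, self.V, self.b]

    def n_parameters(self) -> int:
        return 4 * (self.n_input * self.n_units + self.n_units**2 + self.n_units)

    def cell_spec(self) -> LSTMCellSpec:
        n = self.n_units
        sl = {"i": slice(0, n), "f": slice(n, 2 * n), "o": slice(2 * n, 3 * n), "c": slice(3 * n, 4 * n)}
        return LSTMCellSpec(
            W={a: self.W[:, sl[a]].T.copy() for a in GATES},
            V={a: self.V[:, sl[a]].T.copy() for a in GATES},
            B={a: self.b[sl[a]].copy() for a in GATES},
        )

    def forward(self, X: np.ndarray):
        """X: (N, T, l) → H: (N, T, n) plus the BPTT cache."""
        N, T, _ = X.shape
        n = self.n_units
        h = np.zeros((N, n))
        c = np.zeros((N, n))
        H = np.empty((N, T, n))
        cache = []
        for t in range(T):
            z = X[:, t] @ self.W + h @ self.V + self.b
            g_i = sigmoid(z[:, :n])
            g_f = sigmoid(z[:, n:2 * n])
            g_o = sigmoid(z[:, 2 * n:3 * n])
            c_bar = np.tanh(z[:, 3 * n:])
            c_new = g_f * c + g_i * c_bar
            tanh_c = np.tanh(c_new)
            h_new = g_o * tanh_c
            cache.append((X[:, t], h, c, g_i, g_f, g_o, c_bar, tanh_c))
            h, c = h_new, c_new
            H[:, t] = h
        return H, cache

    def backward(self, dH: np.ndarray, cache):
        """Gradient of the loss wrt inputs and weights given dLoss/dH."""
        N, T, n = dH.shape
        dW = np.zeros_like(self.W)
        dV = np.zeros_like(self.V)
        db = np.zeros_like(self.b)
        dX = np.empty((N, T, self.n_input))
        dh_next = np.zeros((N, n))
        dc_next = np.zeros((N, n))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, g_i, g_f, g_o, c_bar, tanh_c = cache[t]
            dh = dH[:, t] + dh_next
            dc = dc_next + dh * g_o * (1.0 - tanh_c**2)
            dg_o = dh * tanh_c
            dg_i = dc * c_bar
            dg_f = dc * c_prev
            dc_bar = dc * g_i
            dz = np.concatenate(
                [
                    dg_i * g_i * (1.0 - g_i),
                    dg_f * g_f * (1.0 - g_f),
                    dg_o * g_o * (1.0 - g_o),
                    dc_bar * (1.0 - c_bar**2),
                ],
                axis=1,
            )
            dW += x_t.T @ dz
            dV += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh_next = dz @ self.V.T
            dc_next = dc * g_f
        return dX, [dW, dV, db]


class DenseLayer:
    """Per-timestep linear map (the network's output head)."""

    def __init__(self, n_input: int, n_output: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (n_input + n_output))
        self.W = rng.uniform(-lim, lim, (n_input, n_output))
        self.b = np.zeros(n_output)

    @property
    def params(self):
        return [self.W, self.b]

    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def forward(self, H):
        return H @ self.W + self.b, H

    def backward(self, dY, cache):
        H = cache
        dW = np.einsum("ntk,nto->ko", H, dY)
        db = dY.sum(axis=(0, 1))
        dH = dY @ self.W.T
        return dH, [dW, db]


def _check_mask(pred, target, mask):
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != target.shape or mask.shape != pred.shape[:2]:
        raise ValueError("prediction, target and mask shapes are inconsistent")
    lengths = mask.sum(axis=1)
    if np.any(lengths == 0):
        raise ValueError("every sequence needs at least one unmasked step")
    return pred, target, mask, lengths


def masked_mse(pred, target, mask) -> float:
    """Ẽ: mean over sequences of the per-sequence mean (over its real steps)
    of the squared error norm ‖t − t̂‖² summed over output features."""
    pred, target, mask, lengths = _check_mask(pred, target, mask)
    e = ((pred - target) ** 2).sum(axis=-1)
    per_seq = (e * mask).sum(axis=1) / lengths
    return float(per_seq.mean())


def masked_mse_grad(pred, target, mask) -> np.ndarray:
    """dẼ/dt̂, zero on padded steps."""
    pred, target, mask, lengths = _check_mask(pred, target, mask)
    N = pred.shape[0]
    scale = (mask / lengths[:, None])[:, :, None] / N
    return 2.0 * (pred - target) * scale


class Adam:
    """Adam with the standard bias-corrected moment estimates.

    ``clip_norm`` rescales each update's gradients to a maximum global norm,
    which suppresses the occasional loss surge of small-batch training.
    """

    def __init__(self, params: list[np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.clip_norm is not None:
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if gnorm > self.clip_norm:
                grads = [g * (self.clip_norm / gnorm) for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
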