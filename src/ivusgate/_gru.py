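"""Compact numpy bidirectional GRU with manual backpropagation.

One GRU layer per direction processes the 64-step scalar input sequence;
the two final hidden states are concatenated and mapped through a dense
layer and a logistic sigmoid to a single probability. Gradients are
computed by hand (backpropagation through time) and applied with Adam.
Everything is vectorized over the batch dimension, so training at batch
size 1 or 64 uses the same code path.

Gate equations (per step, arrays are batch-major):

    r = sigmoid(x Wxr + h Whr + br)
    z = sigmoid(x Wxz + h Whz + bz)
    c = tanh(x Wxc + r * (h Whc) + bc)
    h' = (1 - z) * c + z * h

The three gates are stored stacked along the last axis (order r, z, c) in
``Wx (in, 3H)``, ``Wh (H, 3H)``, ``bx/bh (3H,)``.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_params(rng: np.random.Generator, input_size: int, hidden_size: int) -> dict:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) initialization for every tensor."""
    bound = 1.0 / np.sqrt(hidden_size)

    def u(*shape):
        return rng.uniform(-bound, bound, size=shape)

    params = {}
    for d in ("fwd", "bwd"):
        params[f"{d}_Wx"] = u(input_size, 3 * hidden_size)
        params[f"{d}_Wh"] = u(hidden_size, 3 * hidden_size)
        params[f"{d}_bx"] = u(3 * hidden_size)
        params[f"{d}_bh"] = u(3 * hidden_size)
    params["out_W"] = u(2 * hidden_size, 1)
    params["out_b"] = u(1)
    return params


def _gru_forward(x: np.ndarray, Wx, Wh, bx, bh):
    """Run one direction over ``x (B, T, in)``; return final state and cache."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    cache = []
    gx_all = x @ Wx + bx  # (B, T, 3H)
    for t in range(T):
        gx = gx_all[:, t]
        gh = h @ Wh + bh
        r = _sigmoid(gx[:, :H] + gh[:, :H])
        z = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
        ghc = gh[:, 2 * H :]
        c = np.tanh(gx[:, 2 * H :] + r * ghc)
        h_new = (1.0 - z) * c + z * h
        cache.append((h, r, z, c, ghc))
        h = h_new
    return h, cache


def _gru_backward(dh_final: np.ndarray, x: np.ndarray, Wx, Wh, cache):
    """BPTT for one direction; returns parameter gradients (no input grads)."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    dbx = np.zeros(3 * H)
    dbh = np.zeros(3 * H)
    dh = dh_final
    for t in range(T - 1, -1, -1):
        h_prev, r, z, c, ghc = cache[t]
        dc = dh * (1.0 - z)
        dz = dh * (h_prev - c)
        dh_prev = dh * z
        da_c = dc * (1.0 - c * c)  # pre-tanh
        dr = da_c * ghc
        da_r = dr * r * (1.0 - r)
        da_z = dz * z * (1.0 - z)
        dgx = np.concatenate([da_r, da_z, da_c], axis=1)
        dgh = np.concatenate([da_r, da_z, da_c * r], axis=1)
        dWx += x[:, t].T @ dgx
        dWh += h_prev.T @ dgh
        dbx += dgx.sum(axis=0)
        dbh += dgh.sum(axis=0)
        dh = dh_prev + dgh @ Wh.T
    return dWx, dWh, dbx, dbh


def predict(params: dict, x: np.ndarray) -> np.ndarray:
    """Probabilities for a batch of windows ``x (B, T, in)`` -> ``(B,)``."""
    h_f, _ = _gru_forward(x, params["fwd_Wx"], params["fwd_Wh"], params["fwd_bx"], params["fwd_bh"])
    h_b, _ = _gru_forward(
        x[:, ::-1], params["bwd_Wx"], params["bwd_Wh"], params["bwd_bx"], params["bwd_bh"]
    )
    feat = np.concatenate([h_f, h_b], axis=1)
    return _sigmoid(feat @ params["out_W"] + params["out_b"])[:, 0]


def loss_and_grads(params: dict, x: np.ndarray, y: np.ndarray):
    """Mean-square-error loss over the batch and gradients for every tensor."""
    B = x.shape[0]
    xr = x[:, ::-1]
    h_f, cache_f = _gru_forward(
        x, params["fwd_Wx"], params["fwd_Wh"], params["fwd_bx"], params["fwd_bh"]
    )
    h_b, cache_b = _gru_forward(
        xr, params["bwd_Wx"], params["bwd_Wh"], params["bwd_bx"], params["bwd_bh"]
    )
    feat = np.concatenate([h_f, h_b], axis=1)
    logits = feat @ params["out_W"] + params["out_b"]
    p = _sigmoid(logits)[:, 0]
    loss = float(np.mean((p - y) ** 2))

    dp = 2.0 * (p - y) / B
    dlogit = (dp * p * (1.0 - p))[:, None]
    grads = {
        "out_W": feat.T @ dlogit,
        "out_b": dlogit.sum(axis=0),
    }
    dfeat = dlogit @ params["out_W"].T
    H = h_f.shape[1]
    for d, xin, cache, dh in (
        ("fwd", x, cache_f, dfeat[:, :H]),
        ("bwd", xr, cache_b, dfeat[:, H:]),
    ):
        dWx, dWh, dbx, dbh = _gru_backward(dh, xin, params[f"{d}_Wx"], params[f"{d}_Wh"], cache)
        grads[f"{d}_Wx"] = dWx
        grads[f"{d}_Wh"] = dWh
        grads[f"{d}_bx"] = dbx
        grads[f"{d}_bh"] = dbh
    return loss, p, grads


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
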