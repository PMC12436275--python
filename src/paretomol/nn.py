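"""Minimal numpy neural-network layers for sequence modelling.

Implements exactly what the SMILES generator needs — embedding, LSTM,
linear, ReLU, causal multi-head self-attention, softmax cross-entropy
and Adam — with hand-written backprop. Layers follow a forward/backward
protocol: ``forward`` caches what ``backward`` needs; ``backward`` takes
the gradient w.r.t. the output and accumulates parameter gradients.

Stepwise (single-token) forward passes are provided for autoregressive
sampling; they share parameters with the batched training path.
"""

from __future__ import annotations

import numpy as np

#: Training dtype. float32 halves memory traffic and roughly doubles BLAS
#: throughput; gradient-check tests build layers in float64 for precision.
DEFAULT_DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray, dtype=None):
        self.value = value.astype(DEFAULT_DTYPE if dtype is None else dtype)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adam optimizer over a list of Params (beta1=0.9, beta2=0.999).

    Gradients are clipped to a global L2 norm before the update — the
    usual safeguard against the occasional exploding gradient in
    recurrent nets, which otherwise makes training outcomes erratic.
    """

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                                for p in self.params))
            if total > self.clip_norm:
                factor = self.clip_norm / total
                for p in self.params:
                    p.grad *= factor
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad ** 2
            p.value -= self.lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            dtype=None) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound,
                       size=(fan_in, fan_out)).astype(
                           DEFAULT_DTYPE if dtype is None else dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Embedding:
    def __init__(self, rng: np.random.Generator, vocab_size: int, dim: int,
                 dtype=None):
        self.W = Param(rng.normal(0.0, 0.1, size=(vocab_size, dim)), dtype)
        self._idx: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, idx: np.ndarray) -> np.ndarray:
        self._idx = idx
        return self.W.value[idx]

    def backward(self, dout: np.ndarray) -> None:
        np.add.at(self.W.grad, self._idx, dout)

    def step(self, idx: np.ndarray) -> np.ndarray:
        return self.W.value[idx]


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 dtype=None):
        self.W = Param(_glorot(rng, d_in, d_out), dtype)
        self.b = Param(np.zeros(d_out), dtype)
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dout.reshape(-1, dout.shape[-1])
        self.b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.W.value.T

    def step(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.value + self.b.value


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def step(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0.0)


class LSTM:
    """Single LSTM layer, batch-first. Gates ordered i, f, g, o."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int,
                 dtype=None):
        self.d_in = d_in
        self.hidden = hidden
        self.W = Param(_glorot(rng, d_in, 4 * hidden), dtype)
        self.U = Param(_glorot(rng, hidden, 4 * hidden), dtype)
        self.b = Param(np.zeros(4 * hidden), dtype)
        # forget-gate bias 1: standard trick for gradient flow early in training
        self.b.value[hidden:2 * hidden] = 1.0
        self._cache: dict | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.U, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, d_in) -> h: (B, T, hidden); initial state zero."""
        B, T, _ = x.shape
        H = self.hidden
        dt = self.W.value.dtype
        i = np.empty((B, T, H), dt); f = np.empty((B, T, H), dt)
        g = np.empty((B, T, H), dt); o = np.empty((B, T, H), dt)
        c = np.empty((B, T, H), dt); h = np.empty((B, T, H), dt)
        tanh_c = np.empty((B, T, H), dt)
        xW = x @ self.W.value + self.b.value  # precompute input contribution
        h_prev = np.zeros((B, H), dt)
        c_prev = np.zeros((B, H), dt)
        for t in range(T):
            z = xW[:, t] + h_prev @ self.U.value
            i[:, t] = _sigmoid(z[:, :H])
            f[:, t] = _sigmoid(z[:, H:2 * H])
            g[:, t] = np.tanh(z[:, 2 * H:3 * H])
            o[:, t] = _sigmoid(z[:, 3 * H:])
            c[:, t] = f[:, t] * c_prev + i[:, t] * g[:, t]
            tanh_c[:, t] = np.tanh(c[:, t])
            h[:, t] = o[:, t] * tanh_c[:, t]
            h_prev = h[:, t]
            c_prev = c[:, t]
        self._cache = dict(x=x, i=i, f=f, g=g, o=o, c=c, h=h, tanh_c=tanh_c)
        return h

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        cache = self._cache
        x, i, f, g, o = cache["x"], cache["i"], cache["f"], cache["g"], cache["o"]
        c, h, tanh_c = cache["c"], cache["h"], cache["tanh_c"]
        B, T, H = h.shape
        dt = h.dtype
        dz_all = np.empty((B, T, 4 * H), dt)
        dh_next = np.zeros((B, H), dt)
        dc_next = np.zeros((B, H), dt)
        for t in range(T - 1, -1, -1):
            dh = dh_out[:, t] + dh_next
            do = dh * tanh_c[:, t]
            dc = dh * o[:, t] * (1 - tanh_c[:, t] ** 2) + dc_next
            c_prev = c[:, t - 1] if t > 0 else np.zeros((B, H), dt)
            di = dc * g[:, t]
            df = dc * c_prev
            dg = dc * i[:, t]
            dz = np.concatenate(
                [di * i[:, t] * (1 - i[:, t]),
                 df * f[:, t] * (1 - f[:, t]),
                 dg * (1 - g[:, t] ** 2),
                 do * o[:, t] * (1 - o[:, t])], axis=1)
            dz_all[:, t] = dz
            dh_next = dz @ self.U.value.T
            dc_next = dc * f[:, t]
        dz_flat = dz_all.reshape(-1, 4 * H)
        self.W.grad += x.reshape(-1, self.d_in).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        h_prev = np.concatenate([np.zeros((B, 1, H), dt), h[:, :-1]], axis=1)
        self.U.grad += h_prev.reshape(-1, H).T @ dz_flat
        dx = dz_all @ self.W.value.T
        return dx

    def init_state(self, batch: int) -> tuple[np.ndarray, np.ndarray]:
        dt = self.W.value.dtype
        return (np.zeros((batch, self.hidden), dt),
                np.zeros((batch, self.hidden), dt))

    def step(self, x_t: np.ndarray, state: tuple[np.ndarray, np.ndarray]):
        h_prev, c_prev = state
        H = self.hidden
        z = x_t @ self.W.value + h_prev @ self.U.value + self.b.value
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return h, (h, c)


def _softmax_last(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


class CausalSelfAttention:
    """Multi-head scaled dot-product self-attention with a causal mask.

    Width = heads * d_k; per head, softmax(Q W_q (K W_k)^T / sqrt(d_k))
    applied to V W_v, heads concatenated and projected by W_o. The causal
    mask keeps position t blind to positions > t so that training and
    step-by-step sampling see the same distribution.
    """

    def __init__(self, rng: np.random.Generator, heads: int, d_k: int,
                 dtype=None):
        self.heads = heads
        self.d_k = d_k
        self.width = heads * d_k
        W = self.width
        self.Wq = Param(_glorot(rng, W, W), dtype)
        self.Wk = Param(_glorot(rng, W, W), dtype)
        self.Wv = Param(_glorot(rng, W, W), dtype)
        self.Wo = Param(_glorot(rng, W, W), dtype)
        self._cache: dict | None = None

    @property
    def params(self) -> list[Param]:
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * d)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, W = x.shape
        q = self._split(x @ self.Wq.value)
        k = self._split(x @ self.Wk.value)
        v = self._split(x @ self.Wv.value)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        mask = np.triu(np.ones((T, T), dtype=bool), k=1)
        scores[:, :, mask] = np.finfo(scores.dtype).min / 4
        attn = _softmax_last(scores)
        ctx = attn @ v  # (B, h, T, d_k)
        merged = self._merge(ctx)
        out = merged @ self.Wo.value
        self._cache = dict(x=x, q=q, k=k, v=v, attn=attn, merged=merged)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self._cache
        x, q, k, v, attn, merged = c["x"], c["q"], c["k"], c["v"], c["attn"], c["merged"]
        B, T, W = x.shape
        self.Wo.grad += merged.reshape(-1, W).T @ dout.reshape(-1, W)
        dmerged = dout @ self.Wo.value.T
        dctx = self._split(dmerged)
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        ds /= np.sqrt(self.d_k)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        dq_m = self._merge(dq)
        dk_m = self._merge(dk)
        dv_m = self._merge(dv)
        x_flat = x.reshape(-1, W)
        self.Wq.grad += x_flat.T @ dq_m.reshape(-1, W)
        self.Wk.grad += x_flat.T @ dk_m.reshape(-1, W)
        self.Wv.grad += x_flat.T @ dv_m.reshape(-1, W)
        return (dq_m @ self.Wq.value.T + dk_m @ self.Wk.value.T
                + dv_m @ self.Wv.value.T)

    def init_state(self, batch: int) -> dict:
        dt = self.Wq.value.dtype
        return {"k": np.zeros((batch, self.heads, 0, self.d_k), dt),
                "v": np.zeros((batch, self.heads, 0, self.d_k), dt)}

    def step(self, x_t: np.ndarray, state: dict) -> tuple[np.ndarray, dict]:
        """x_t: (B, width). Attends over all cached positions plus itself."""
        B = x_t.shape[0]
        q = (x_t @ self.Wq.value).reshape(B, self.heads, 1, self.d_k)
        k_new = (x_t @ self.Wk.value).reshape(B, self.heads, 1, self.d_k)
        v_new = (x_t @ self.Wv.value).reshape(B, self.heads, 1, self.d_k)
        k_all = np.concatenate([state["k"], k_new], axis=2)
        v_all = np.concatenate([state["v"], v_new], axis=2)
        scores = q @ k_all.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        attn = _softmax_last(scores)
        ctx = (attn @ v_all).reshape(B, self.width)
        return ctx @ self.Wo.value, {"k": k_all, "v": v_all}


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          mask: np.ndarray,
                          seq_weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Masked sequence cross-entropy, averaged over the batch.

    loss = (1/B) sum_b w_b sum_t mask_bt * -log p(target_bt)

    Returns the scalar loss and d(loss)/d(logits).
    """
    B, T, V = logits.shape
    probs = _softmax_last(logits)
    logp = np.log(np.maximum(
        probs[np.arange(B)[:, None], np.arange(T)[None, :],
              targets].astype(np.float64), 1e-300))
    w = np.ones(B) if seq_weights is None else seq_weights
    loss = float(-(w[:, None] * mask * logp).sum() / B)
    dlogits = probs.copy()
    dlogits[np.arange(B)[:, None], np.arange(T)[None, :], targets] -= 1.0
    dlogits *= (w[:, None] * mask)[..., None] / B
    return loss, dlogits
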