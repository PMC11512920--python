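"""Minimal NumPy neural-network engine for the two-stage sequence classifier.

Implements exactly the layers the classifier needs -- 2-D convolution, batch
normalisation, ReLU, a stacked LSTM, dropout, linear layers -- with manual
backpropagation and an Adam optimiser.  The model sizes used in this package
are small (tens of thousands of parameters, cohorts of tens of subjects), so
plain vectorised NumPy on one CPU is entirely adequate.

Conventions: images are NCHW batches; sequences are (batch, time, features);
convolutions are cross-correlations in the deep-learning convention (the
textbook flipped-kernel convolution is the same operation with the kernel
reversed, which is immaterial for learned weights); LSTM gates follow the
standard forget/input/candidate/output equations with sigmoid gate
activations and tanh cell activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "Conv2d", "BatchNorm2d", "ReLU", "LSTM", "Dropout", "Linear",
    "Adam", "softmax", "cross_entropy",
]


class Parameter:
    """A weight array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, shape)


class Conv2d:
    """2-D convolution (cross-correlation) with stride and symmetric zero
    padding ``(kernel - 1) // 2``; odd kernels only."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("odd kernel sizes only")
        fan_in = in_channels * kernel * kernel
        self.W = Parameter(_uniform(rng, (out_channels, in_channels, kernel,
                                          kernel), fan_in))
        self.b = Parameter(_uniform(rng, (out_channels,), fan_in))
        self.stride = stride
        self.kernel = kernel
        self.pad = (kernel - 1) // 2
        self._cache = None

    def out_size(self, size: int) -> int:
        return (size + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        s, k, p = self.stride, self.kernel, self.pad
        Ho, Wo = self.out_size(H), self.out_size(Wd)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        y = np.tile(self.b.value[None, :, None, None], (B, 1, Ho, Wo))
        Wv = self.W.value
        for u in range(k):
            for v in range(k):
                patch = xp[:, :, u:u + s * Ho:s, v:v + s * Wo:s]
                y += np.einsum("bchw,kc->bkhw", patch, Wv[:, :, u, v])
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        B, C, H, Wd = x_shape
        s, k = self.stride, self.kernel
        Ho, Wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros_like(xp)
        Wv = self.W.value
        for u in range(k):
            for v in range(k):
                patch = xp[:, :, u:u + s * Ho:s, v:v + s * Wo:s]
                self.W.grad[:, :, u, v] += np.einsum("bkhw,bchw->kc", dy, patch)
                dxp[:, :, u:u + s * Ho:s, v:v + s * Wo:s] += np.einsum(
                    "bkhw,kc->bchw", dy, Wv[:, :, u, v])
        self.b.grad += dy.sum(axis=(0, 2, 3))
        p = self.pad
        return dxp[:, :, p:p + H, p:p + Wd]

    def parameters(self):
        return [self.W, self.b]


class BatchNorm2d:
    """Per-channel batch normalisation over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, train)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dy * g * ivar[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        del n
        return term * ivar[None, :, None, None]

    def parameters(self):
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)

    def parameters(self):
        return []


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM:
    """One LSTM layer processed over a full (batch, time, features) sequence.

    Gate pre-activations are ``z = x W_x + h_prev W_h + b`` split into input,
    forget, candidate and output gates::

        i = sigmoid(z_i)        f = sigmoid(z_f)
        g = tanh(z_g)           o = sigmoid(z_o)
        c = f * c_prev + i * g
        h = o * tanh(c)

    The forget-gate bias is initialised to +1 (standard remedy against early
    forgetting).
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator):
        H = hidden_size
        self.Wx = Parameter(_uniform(rng, (input_size, 4 * H), H))
        self.Wh = Parameter(_uniform(rng, (H, 4 * H), H))
        b = _uniform(rng, (4 * H,), H)
        b[H:2 * H] += 1.0
        self.b = Parameter(b)
        self.hidden_size = H
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        steps = []
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            ct = np.tanh(c_new)
            h_new = o * ct
            steps.append((x[:, t], h, c, i, f, g, o, ct))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = steps
        return hs

    def step(self, x: np.ndarray, h: np.ndarray, c: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
        """Single inference step (no caching): returns the new (h, c)."""
        H = self.hidden_size
        z = x @ self.Wx.value + h @ self.Wh.value + self.b.value
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        return o * np.tanh(c_new), c_new

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        steps = self._cache
        B, T, H = dhs.shape
        dx = np.empty((B, T, self.Wx.value.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, ct = steps[t]
            dh = dhs[:, t] + dh_next
            do = dh * ct
            dc = dc_next + dh * o * (1.0 - ct * ct)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            self.Wx.grad += xt.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
        return dx

    def parameters(self):
        return [self.Wx, self.Wh, self.b]


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def parameters(self):
        return []


class Linear:
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.W = Parameter(_uniform(rng, (in_features, out_features), in_features))
        self.b = Parameter(_uniform(rng, (out_features,), in_features))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray,
                  class_weights: np.ndarray | None = None
                  ) -> tuple[float, np.ndarray]:
    """Mean (optionally class-weighted) cross-entropy and its logit gradient."""
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[y]
    loss = float(np.sum(w * -np.log(p[np.arange(n), y] + 1e-12)) / w.sum())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits


class Adam:
    """Adam with bias correction; one slot pair per parameter."""

    def __init__(self, parameters, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.parameters = list(parameters)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.parameters]
        self.v = [np.zeros_like(p.value) for p in self.parameters]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.parameters, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.zero_grad()
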