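"""Neural-network layers for 1-D sequence models.

Convolutions and the LSTM recurrence are implemented as fused graph nodes
with hand-written backward passes (verified against finite differences in
the test suite); everything else is composed from the autodiff primitives.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, sqrt as t_sqrt


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self):
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self):
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()
        return self

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LSTM(Module):
    """Single-layer LSTM returning the full hidden sequence.

    Gate order inside the packed weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at +1.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        s = 1.0 / np.sqrt(hidden)
        self.Wx = Tensor(rng.uniform(-s, s, size=(n_in, 4 * hidden)), requires_grad=True)
        self.Wh = Tensor(rng.uniform(-s, s, size=(hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden

    def forward(self, x: Tensor) -> Tensor:
        """x: (batch, T, n_in) -> hidden sequence (batch, T, hidden)."""
        H = self.hidden
        Wx, Wh, b = self.Wx, self.Wh, self.b
        xd = x.data
        B, T, _ = xd.shape
        sig = lambda a: 1.0 / (1.0 + np.exp(-a))

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        cache = []  # per step: (i, f, g, o, c_prev, h_prev, tanh_c)
        for t in range(T):
            a = xd[:, t] @ Wx.data + h @ Wh.data + b.data
            i = sig(a[:, :H])
            f = sig(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sig(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            Hs[:, t] = h
            cache.append((i, f, g, o, c_prev, h_prev, tc))

        def bwd(gH):
            dx = np.zeros_like(xd)
            dWx = np.zeros_like(Wx.data)
            dWh = np.zeros_like(Wh.data)
            db = np.zeros_like(b.data)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i, f, g, o, c_prev, h_prev, tc = cache[t]
                dh = gH[:, t] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc ** 2)
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc_next = dc * f
                da = np.concatenate([
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ], axis=1)
                dx[:, t] = da @ Wx.data.T
                dh_next = da @ Wh.data.T
                dWx += xd[:, t].T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
            return (dx, dWx, dWh, db)

        return Tensor._node(Hs, (x, Wx, Wh, b), bwd)


# -- 1-D convolutions ----------------------------------------------------------

def _conv_out_len(L: int, K: int, stride: int, pad: int) -> int:
    return (L + 2 * pad - K) // stride + 1


def _conv_fwd(x, w, stride, pad):
    B, Ci, L = x.shape
    Co, _, K = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    Lout = _conv_out_len(L, K, stride, pad)
    y = np.zeros((B, Co, Lout))
    for k in range(K):
        xs = xp[:, :, k:k + stride * Lout:stride]
        y += np.matmul(w[:, :, k], xs)
    return y


def _conv_bwd_x(dy, w, stride, pad, L):
    B, Co, Lout = dy.shape
    _, Ci, K = w.shape
    dxp = np.zeros((B, Ci, L + 2 * pad))
    for k in range(K):
        dxp[:, :, k:k + stride * Lout:stride] += np.matmul(w[:, :, k].T, dy)
    return dxp[:, :, pad:pad + L]


def _conv_bwd_w(dy, x, stride, pad, K):
    B, Co, Lout = dy.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    Ci = x.shape[1]
    dw = np.zeros((Co, Ci, K))
    for k in range(K):
        xs = xp[:, :, k:k + stride * Lout:stride]
        dw[:, :, k] = np.tensordot(dy, xs, axes=([0, 2], [0, 2]))
    return dw


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, pad: int = 1):
        super().__init__()
        self.W = Tensor(rng.normal(0.0, 0.02, size=(c_out, c_in, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad, self.kernel = stride, pad, kernel

    def forward(self, x: Tensor) -> Tensor:
        W, b, stride, pad = self.W, self.b, self.stride, self.pad
        xd = x.data
        y = _conv_fwd(xd, W.data, stride, pad) + b.data[None, :, None]
        L, K = xd.shape[2], self.kernel

        def bwd(g):
            return (_conv_bwd_x(g, W.data, stride, pad, L),
                    _conv_bwd_w(g, xd, stride, pad, K),
                    g.sum(axis=(0, 2)))

        return Tensor._node(y, (x, W, b), bwd)


class ConvTranspose1d(Module):
    """Fractional-strided convolution; with kernel 4, stride 2, pad 1 it
    exactly doubles the sequence length."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, pad: int = 1):
        super().__init__()
        self.W = Tensor(rng.normal(0.0, 0.02, size=(c_in, c_out, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad, self.kernel = stride, pad, kernel

    def forward(self, x: Tensor) -> Tensor:
        W, b, s, p, K = self.W, self.b, self.stride, self.pad, self.kernel
        xd = x.data
        B, Ci, L = xd.shape
        Co = W.data.shape[1]
        Lfull = (L - 1) * s + K
        yp = np.zeros((B, Co, Lfull))
        for k in range(K):
            yp[:, :, k:k + s * L:s] += np.matmul(W.data[:, :, k].T, xd)
        y = yp[:, :, p:Lfull - p] + b.data[None, :, None]

        def bwd(g):
            gp = np.pad(g, ((0, 0), (0, 0), (p, p)))
            dx = np.zeros_like(xd)
            dW = np.zeros_like(W.data)
            for k in range(K):
                gs = gp[:, :, k:k + s * L:s]
                dx += np.matmul(W.data[:, :, k], gs)
                dW[:, :, k] = np.tensordot(xd, gs, axes=([0, 2], [0, 2]))
            return (dx, dW, g.sum(axis=(0, 2)))

        return Tensor._node(y, (x, W, b), bwd)


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, length) for (B, C, L) inputs.

    Running statistics are used in eval mode so metric evaluation is
    deterministic and independent of the evaluation batch.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        C = self.channels
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(C)
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1))
            var = Tensor(self.running_var.reshape(1, C, 1))
        xhat = (x - mu) / t_sqrt(var + self.eps)
        return self.gamma.reshape(1, C, 1) * xhat + self.beta.reshape(1, C, 1)
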