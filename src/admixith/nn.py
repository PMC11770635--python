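"""Minimal numpy neural-network backend for the patch classifier.

Implements exactly what the desk-scale classifier needs: 3x3 same-padding
convolutions (via im2col), batch normalization, ReLU, 2x2 max pooling, a
linear head, and Adam with decoupled weight decay.  Arrays are NCHW
float32/float64; forward passes cache what backward needs.  The network is
small (~100k parameters) by design: what the pipeline certifies is the
training mechanism (noise-robust loss, pruning, calibration-based model
selection), not model capacity.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "Adam"]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches for a 3x3 stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


def _col2im3(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + w] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:h + 1, 1:w + 1]


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0, scale, size=(c_in * 9, c_out))
        self.b = np.zeros(c_out)
        self.decay = (True, False)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col3(x)
        n, _, h, w = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        return _col2im3(dflat @ self.W.T, self._shape)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm:
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.decay = (False, False)
        self._accum: list | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
            if self._accum is not None:
                cnt = x.shape[0] * x.shape[2] * x.shape[3]
                self._accum[0] += cnt
                self._accum[1] += x.sum(axis=(0, 2, 3))
                self._accum[2] += (x ** 2).sum(axis=(0, 2, 3))
        else:
            mean, var = self.run_mean, self.run_var
        m, v = mean[None, :, None, None], var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n_eff = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        # standard batchnorm backward, reduced over (N, H, W) per channel
        t1 = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (t1 - t2) * self._istd[None, :, None, None]

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class MaxPool2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        dxr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.decay = (True, False)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class SmallCNN:
    """4 conv-BN-ReLU-pool blocks + linear head for 2-class logits.

    Expects square inputs whose side is divisible by 16 (default 32), NCHW.
    """

    def __init__(self, input_size: int = 32, channels: tuple[int, ...] = (16, 32, 64, 128),
                 n_classes: int = 2, seed: int = 0):
        if input_size % 2 ** len(channels):
            raise ValueError("input_size must be divisible by 2^n_blocks")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.layers: list = []
        c_in = 3
        for c_out in channels:
            self.layers += [Conv3x3(c_in, c_out, rng), BatchNorm(c_out),
                            ReLU(), MaxPool2()]
            c_in = c_out
        side = input_size // 2 ** len(channels)
        self.head = Linear(c_in * side * side, n_classes, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        self._feat_shape = x.shape
        return self.head.forward(x.reshape(x.shape[0], -1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits).reshape(self._feat_shape)
        for layer in reversed(self.layers):
            dx = layer.backward(dx)

    # -- parameter plumbing ------------------------------------------------
    def _modules(self):
        return self.layers + [self.head]

    def params(self) -> list[np.ndarray]:
        return [p for m in self._modules() for p in m.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for m in self._modules() for g in m.grads()]

    def decay_flags(self) -> list[bool]:
        return [f for m in self._modules() if m.params()
                for f in getattr(m, "decay", (False,) * len(m.params()))]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 256) -> None:
        """Set BN running statistics to exact full-dataset activation moments.

        With few batches per epoch the exponentially averaged running stats
        lag far behind the rapidly training weights, making eval-mode
        predictions stale; one calibration pass after each epoch removes
        that gap deterministically.
        """
        bns = [m for m in self._modules() if isinstance(m, BatchNorm)]
        for bn in bns:
            bn._accum = [0, np.zeros_like(bn.run_mean), np.zeros_like(bn.run_var)]
        for i in range(0, len(x), batch_size):
            self.forward(x[i:i + batch_size], train=True)
        for bn in bns:
            cnt, s, ssq = bn._accum
            mean = s / cnt
            bn.run_mean = mean
            bn.run_var = np.maximum(ssq / cnt - mean ** 2, 0.0)
            bn._accum = None

    def get_state(self) -> dict:
        state = {"params": [p.copy() for p in self.params()], "bn": []}
        for m in self._modules():
            if isinstance(m, BatchNorm):
                state["bn"].append((m.run_mean.copy(), m.run_var.copy()))
        return state

    def set_state(self, state: dict) -> None:
        for p, saved in zip(self.params(), state["params"]):
            p[...] = saved
        bn_iter = iter(state["bn"])
        for m in self._modules():
            if isinstance(m, BatchNorm):
                m.run_mean, m.run_var = (a.copy() for a in next(bn_iter))


class Adam:
    """Adam with decoupled weight decay applied to flagged parameters."""

    def __init__(self, model: SmallCNN, lr: float = 1e-4, weight_decay: float = 0.2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.params()]
        self.v = [np.zeros_like(p) for p in model.params()]

    def step(self) -> None:
        self.t += 1
        flags = self.model.decay_flags()
        for p, g, m, v, decay in zip(self.model.params(), self.model.grads(),
                                     self.m, self.v, flags):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if decay:
                p -= self.lr * self.wd * p
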