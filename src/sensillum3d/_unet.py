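"""A small numpy U-Net: encoder–decoder with skip connections.

Pure-numpy implementation (im2col convolutions with hand-derived backward
passes, Adam, binary cross-entropy on logits) sized for desk-scale phantom
segmentation. Deterministic for a fixed seed and thread count.

Gradient correctness of every layer is checked against finite differences in
the test suite.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "Adam", "bce_with_logits", "sigmoid"]

_DTYPE = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.astype(float)
    y = targets.astype(float)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad.astype(_DTYPE)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches for a 3x3 same-padding convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


class _Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding, optional ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        self.c_in, self.c_out, self.relu = c_in, c_out, relu
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(scale=std, size=(c_in * 9, c_out)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, h, w = x.shape
        cols = _im2col3(x)
        out = cols @ self.W + self.b
        out = out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        if self.relu:
            mask = out > 0
            out = out * mask
        else:
            mask = None
        if train:
            self._cache = (cols, mask, (n, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, mask, (n, h, w) = self._cache
        self._cache = None
        if self.relu:
            dout = dout * mask
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.dW = cols.T @ dflat
        self.db = dflat.sum(axis=0)
        # input gradient = same conv of dout with 180deg-rotated, channel-swapped kernels
        w_k = self.W.reshape(self.c_in, 3, 3, self.c_out)
        w_flip = w_k[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(self.c_out * 9, self.c_in)
        dcols = _im2col3(dout)
        dx = (dcols @ w_flip).reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)

    def params(self):
        return [("W", self), ("b", self)]


class _Conv1x1:
    """1x1 convolution producing logits (no activation)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / c_in)
        self.W = rng.normal(scale=std, size=(c_in, c_out)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._cache = x
        return np.einsum("nchw,cf->nfhw", x, self.W, optimize=True) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        self.dW = np.einsum("nchw,nfhw->cf", x, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        return np.einsum("nfhw,cf->nchw", dout, self.W, optimize=True)


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = blocks.max(axis=(3, 5))
    mask = blocks == out[:, :, :, None, :, None]
    # break ties so gradient flows to exactly one source pixel; block axes
    # (3, 5) are interleaved with spatial axes, so group them before cumsum
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return out, np.ascontiguousarray(mask)


def _maxpool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, c, hh, _, ww, _ = mask.shape
    return (mask * dout[:, :, :, None, :, None]).reshape(n, c, hh * 2, ww * 2)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Encoder–decoder with skip connections for binary segmentation.

    ``depth`` downsampling levels with ``base_filters * 2**i`` channels at
    level i; nearest-neighbour upsampling and channel concatenation on the
    decoder path; a 1x1 conv head emitting per-pixel logits.
    """

    def __init__(self, depth: int = 4, base_filters: int = 16, in_channels: int = 1,
                 seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_filters = base_filters
        filters = [base_filters * 2**i for i in range(depth + 1)]
        self.enc = []
        c_in = in_channels
        for f in filters[:-1]:
            self.enc.append((_Conv3x3(c_in, f, rng), _Conv3x3(f, f, rng)))
            c_in = f
        self.bottleneck = (_Conv3x3(c_in, filters[-1], rng), _Conv3x3(filters[-1], filters[-1], rng))
        self.dec = []
        c_up = filters[-1]
        for f in reversed(filters[:-1]):
            self.dec.append((_Conv3x3(c_up + f, f, rng), _Conv3x3(f, f, rng)))
            c_up = f
        self.head = _Conv1x1(filters[0], 1, rng)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) with H, W divisible by 2**depth. Returns logits (N, H, W)."""
        x = x.astype(_DTYPE)
        if x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2:]
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(f"input size {h}x{w} not divisible by 2**{self.depth}")
        skips, masks = [], []
        for c1, c2 in self.enc:
            x = c2.forward(c1.forward(x, train), train)
            skips.append(x)
            x, m = _maxpool2(x)
            masks.append(m)
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x, train), train)
        self._skip_channels = []
        for (c1, c2), skip in zip(self.dec, reversed(skips)):
            x = _upsample2(x)
            self._skip_channels.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = c2.forward(c1.forward(x, train), train)
        logits = self.head.forward(x, train)
        if train:
            self._masks = masks
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None].astype(_DTYPE))
        dskips = []
        for (c1, c2), (n_up, n_skip) in zip(reversed(self.dec), reversed(self._skip_channels)):
            d = c1.backward(c2.backward(d))
            dskips.append(d[:, n_up:])
            d = _upsample2_backward(d[:, :n_up])
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d))
        for (c1, c2), mask, dskip in zip(reversed(self.enc), reversed(self._masks),
                                         reversed(dskips)):
            d = _maxpool2_backward(d, mask) + dskip
            d = c1.backward(c2.backward(d))
        self._masks = None

    # -- parameter plumbing --------------------------------------------------
    def _convs(self):
        for c1, c2 in self.enc:
            yield c1
            yield c2
        yield self.bottleneck[0]
        yield self.bottleneck[1]
        for c1, c2 in self.dec:
            yield c1
            yield c2
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        out = []
        for conv in self._convs():
            out.extend([conv.W, conv.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for conv in self._convs():
            out.extend([conv.dW, conv.db])
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for conv in self._convs():
            conv.W = next(it).astype(_DTYPE)
            conv.b = next(it).astype(_DTYPE)

    def snapshot(self) -> list[np.ndarray]:
        return copy.deepcopy(self.parameters())

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Per-pixel foreground probabilities for (N, H, W) inputs."""
        x = np.asarray(x, dtype=_DTYPE)
        outs = [sigmoid(self.forward(x[i:i + batch_size], train=False))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs)

    def config(self) -> dict:
        return {"depth": self.depth, "base_filters": self.base_filters}


class Adam:
    """Adam optimizer over a UNet's flat parameter list."""

    def __init__(self, model: UNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in model.parameters()]
        self.v = [np.zeros_like(p) for p in model.parameters()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        params = self.model.parameters()
        grads = self.model.gradients()
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
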