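"""Minimal 1-D convolutional network engine in NumPy.

Implements exactly the building blocks the heart-rate regressor needs:
same-padded strided 1-D convolution, batch normalization, leaky ReLU, mean
squared error with an L2 kernel penalty, and the Adam optimizer.  The
network is small (tens of thousands of parameters), so explicit
im2col-style NumPy operations train it comfortably on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "reference_spec",
    "conv_out_len",
    "Conv1dSame",
    "BatchNorm1d",
    "LeakyReLU",
    "Network",
    "Adam",
    "build",
]


@dataclass(frozen=True)
class LayerSpec:
    """Configuration of one convolutional block."""

    in_channels: int
    out_channels: int
    kernel: int
    stride: int
    batch_norm: bool = True
    activation: str = "leaky_relu"  # or "none"

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        if self.activation not in ("leaky_relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def n_params(self) -> int:
        n = self.kernel * self.in_channels * self.out_channels + self.out_channels
        if self.batch_norm:
            n += 2 * self.out_channels  # scale and shift; running stats not trainable
        return n


@dataclass(frozen=True)
class NetworkSpec:
    """Full network configuration: a stack of conv blocks mapping 400 -> 1."""

    layers: tuple[LayerSpec, ...]
    input_len: int = 400

    def __post_init__(self) -> None:
        last = self.layers[-1]
        if not (last.out_channels == 1 and last.kernel == 1 and not last.batch_norm
                and last.activation == "none"):
            raise ValueError("final layer must be a single filter of kernel size 1, "
                             "without batch norm or activation")
        if self.output_len() != 1:
            raise ValueError("strides must reduce the input length to exactly 1")

    def length_chain(self) -> list[int]:
        lens = [self.input_len]
        for l in self.layers:
            lens.append(conv_out_len(lens[-1], l.stride))
        return lens

    def output_len(self) -> int:
        return self.length_chain()[-1]

    def count_params(self) -> int:
        return sum(l.n_params for l in self.layers)


def conv_out_len(in_len: int, stride: int) -> int:
    """Output length of a same-padded convolution: ceil(in_len / stride)."""
    return -(-in_len // stride)


def reference_spec(width_factor: float = 1.0) -> NetworkSpec:
    """The canonical 11-layer configuration (18,801 parameters at width 1).

    Nine stride-2 layers with kernel 8 collapse 400 samples to a single
    position (400 -> 200 -> 100 -> 50 -> 25 -> 13 -> 7 -> 4 -> 2 -> 1), a
    kernel-7 stride-1 layer mixes the receptive field once more, and a
    single-filter kernel-1 layer reads out the scalar.  ``width_factor``
    scales every hidden channel count without touching the length chain.
    """
    c = max(int(round(16 * width_factor)), 1)
    layers = [LayerSpec(1, c, kernel=8, stride=2)]
    layers += [LayerSpec(c, c, kernel=8, stride=2) for _ in range(8)]
    layers += [LayerSpec(c, c, kernel=7, stride=1)]
    layers += [LayerSpec(c, 1, kernel=1, stride=1, batch_norm=False, activation="none")]
    return NetworkSpec(layers=tuple(layers))


def _same_pad(in_len: int, kernel: int, stride: int) -> tuple[int, int]:
    out_len = conv_out_len(in_len, stride)
    total = max((out_len - 1) * stride + kernel - in_len, 0)
    left = total // 2
    return left, total - left


class Conv1dSame:
    """Same-padded strided 1-D convolution with Glorot-uniform init."""

    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        self.spec = spec
        fan_in = spec.kernel * spec.in_channels
        fan_out = spec.kernel * spec.out_channels
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(spec.out_channels, spec.in_channels, spec.kernel))
        self.b = np.zeros(spec.out_channels)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def kernel_params(self):
        return [self.W]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k, s = self.spec.kernel, self.spec.stride
        n, c, L = x.shape
        left, right = _same_pad(L, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        patches = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        out = np.einsum("nclk,ock->nol", patches, self.W, optimize=True)
        out += self.b[None, :, None]
        if training:
            self._cache = (patches, xp.shape, left, L)
        return out

    def backward(self, dout: np.ndarray):
        patches, xp_shape, left, L = self._cache
        k, s = self.spec.kernel, self.spec.stride
        dW = np.einsum("nclk,nol->ock", patches, dout, optimize=True)
        db = dout.sum(axis=(0, 2))
        dxp = np.zeros(xp_shape)
        dpatch = np.einsum("nol,ock->nclk", dout, self.W, optimize=True)
        L_out = dout.shape[2]
        base = np.arange(L_out) * s
        for kk in range(k):
            np.add.at(dxp, (slice(None), slice(None), base + kk), dpatch[:, :, :, kk])
        dx = dxp[:, :, left : left + L]
        return dx, [dW, db]


class BatchNorm1d:
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def kernel_params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2]
        dgamma = (dout * xhat).sum(axis=(0, 2))
        dbeta = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        dx = (
            inv[None, :, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
            )
        )
        return dx, [dgamma, dbeta]


class LeakyReLU:
    def __init__(self, slope: float = 0.3):
        self.slope = slope
        self._mask = None

    @property
    def params(self):
        return []

    @property
    def kernel_params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x >= 0
        return np.where(x >= 0, x, self.slope * x)

    def backward(self, dout: np.ndarray):
        return np.where(self._mask, dout, self.slope * dout), []


class Network:
    """A sequential stack of conv / batch-norm / activation layers."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, leaky_slope: float = 0.3):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list = []
        for ls in spec.layers:
            self.layers.append(Conv1dSame(ls, rng))
            if ls.batch_norm:
                self.layers.append(BatchNorm1d(ls.out_channels))
            if ls.activation == "leaky_relu":
                self.layers.append(LeakyReLU(leaky_slope))

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def kernel_params(self):
        return [p for layer in self.layers for p in layer.kernel_params]

    def count_params(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (batch, input_len) windows to (batch,) scalars."""
        h = np.asarray(x, dtype=float)[:, None, :]
        for layer in self.layers:
            h = layer.forward(h, training)
        if h.shape[1] != 1 or h.shape[2] != 1:
            raise RuntimeError("network did not reduce to a single scalar per window")
        return h[:, 0, 0]

    def backward(self, dscalar: np.ndarray) -> list[np.ndarray]:
        """Gradients for every parameter, in ``self.params`` order."""
        grads_rev: list[list[np.ndarray]] = []
        d = np.asarray(dscalar, dtype=float)[:, None, None]
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads_rev.append(g)
        grads: list[np.ndarray] = []
        for g in reversed(grads_rev):
            grads.extend(g)
        return grads


def build(spec: NetworkSpec, seed: int = 0, leaky_slope: float = 0.3) -> Network:
    """Construct a network; raises if the spec cannot map input_len to 1."""
    return Network(spec, seed=seed, leaky_slope=leaky_slope)


@dataclass
class Adam:
    """Adam optimizer with framework-default hyperparameters."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    _m: list = field(default_factory=list)
    _v: list = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self._t) / (1 - self.beta1**self._t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
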