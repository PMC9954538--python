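"""Minimal trainable-layer stack on numpy: 2-D convolutions, batch
normalization, pooling, dropout, dense layers, softmax cross-entropy and the
Adam optimizer, with hand-written backward passes.

Conventions follow the common deep-learning layout: 4-D activations are
(batch, channels, height, width); convolutions are cross-correlations with
stride 1 and either "valid" (no padding) or explicit zero padding; every
layer caches what its backward pass needs during ``forward`` and returns the
gradient with respect to its input from ``backward``.  Parameters are plain
float64 arrays so trainable-parameter counts are exact integer bookkeeping.
All randomness (initialization, dropout, batch shuffling) flows through
seeded ``numpy.random.Generator`` objects, making whole training runs
bit-reproducible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "AvgPool2d",
    "MaxPool2d",
    "ELU",
    "Square",
    "SafeLog",
    "Identity",
    "Dropout",
    "Flatten",
    "Linear",
    "CrossEntropyLoss",
    "Adam",
    "count_trainable",
    "get_state",
    "set_state",
]


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.value.shape})"


class Module:
    """Base class: forward/backward pair plus parameter enumeration."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for m in self.children():
            m.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def children(self) -> Iterable["Module"]:
        return []

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def count_trainable(module: Module) -> int:
    """Exact number of trainable scalars, by brute-force enumeration."""
    return int(sum(p.size for p in module.parameters()))


def get_state(module: Module) -> list[np.ndarray]:
    """Snapshot of all parameter values (for checkpointing)."""
    return [p.value.copy() for p in module.parameters()]


def set_state(module: Module, state: Sequence[np.ndarray]) -> None:
    params = module.parameters()
    if len(params) != len(state):
        raise ValueError("state does not match module parameters")
    for p, v in zip(params, state):
        p.value[...] = v


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def children(self) -> Iterable[Module]:
        return self.layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _windows(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, Ho, Wo, kh, kw) view of all valid kh x kw patches."""
    return sliding_window_view(x, (kh, kw), axis=(2, 3))


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    """2-D cross-correlation, stride 1, optional symmetric zero padding.

    ``padding='same'`` keeps the spatial size (kernel dims must be odd or the
    asymmetric remainder is placed at the end, as in common implementations).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: tuple[int, int],
        *,
        bias: bool = True,
        padding: str | tuple[int, int] = (0, 0),
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        if padding == "same":
            # total pad kh-1 split front-heavy like standard same-padding
            self._pad = ((kh - 1) // 2, kh - 1 - (kh - 1) // 2,
                         (kw - 1) // 2, kw - 1 - (kw - 1) // 2)
        else:
            ph, pw = padding
            self._pad = (ph, ph, pw, pw)
        fan_in = in_channels * kh * kw
        self.weight = Parameter(f"{name}.weight",
                                uniform_fan_in(rng, (out_channels, in_channels, kh, kw), fan_in))
        self.bias = Parameter(f"{name}.bias", uniform_fan_in(rng, (out_channels,), fan_in)) if bias else None
        self._x_padded: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad_input(self, x: np.ndarray) -> np.ndarray:
        pt, pb, pl, pr = self._pad
        if pt or pb or pl or pr:
            return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = self._pad_input(x)
        self._x_padded = xp
        kh, kw = self.kernel_size
        win = _windows(xp, kh, kw)  # N, Cin, Ho, Wo, kh, kw
        out = np.einsum("ncxykl,ockl->noxy", win, self.weight.value, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._x_padded
        kh, kw = self.kernel_size
        win = _windows(xp, kh, kw)
        self.weight.grad += np.einsum("ncxykl,noxy->ockl", win, grad, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        # accumulate dX per kernel offset: memory stays O(input), not O(input*k)
        ho, wo = grad.shape[2], grad.shape[3]
        dxp = np.zeros_like(xp)
        w = self.weight.value
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, :, ki:ki + ho, kj:kj + wo] += np.einsum(
                    "noxy,oc->ncxy", grad, w[:, :, ki, kj], optimize=True
                )
        pt, pb, pl, pr = self._pad
        h, w = dxp.shape[2], dxp.shape[3]
        return dxp[:, :, pt:h - pb or None, pl:w - pr or None]


class DepthwiseConv2d(Module):
    """Per-channel convolution with depth multiplier D (grouped, groups=Cin)."""

    def __init__(
        self,
        in_channels: int,
        depth_multiplier: int,
        kernel_size: tuple[int, int],
        *,
        bias: bool = False,
        padding: str | tuple[int, int] = (0, 0),
        rng: np.random.Generator | None = None,
        name: str = "dwconv",
    ):
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel_size
        self.in_channels = in_channels
        self.depth_multiplier = depth_multiplier
        self.kernel_size = (kh, kw)
        if padding == "same":
            self._pad = ((kh - 1) // 2, kh - 1 - (kh - 1) // 2,
                         (kw - 1) // 2, kw - 1 - (kw - 1) // 2)
        else:
            ph, pw = padding
            self._pad = (ph, ph, pw, pw)
        fan_in = kh * kw
        self.weight = Parameter(f"{name}.weight",
                                uniform_fan_in(rng, (in_channels, depth_multiplier, kh, kw), fan_in))
        self.bias = (Parameter(f"{name}.bias",
                               uniform_fan_in(rng, (in_channels * depth_multiplier,), fan_in))
                     if bias else None)
        self._x_padded: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        pt, pb, pl, pr = self._pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if (pt or pb or pl or pr) else x
        self._x_padded = xp
        kh, kw = self.kernel_size
        win = _windows(xp, kh, kw)  # N, C, Ho, Wo, kh, kw
        out = np.einsum("ncxykl,cdkl->ncdxy", win, self.weight.value, optimize=True)
        n, c, d, ho, wo = out.shape
        out = out.reshape(n, c * d, ho, wo)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._x_padded
        kh, kw = self.kernel_size
        c, d = self.in_channels, self.depth_multiplier
        n, _, ho, wo = grad.shape
        g = grad.reshape(n, c, d, ho, wo)
        win = _windows(xp, kh, kw)
        self.weight.grad += np.einsum("ncxykl,ncdxy->cdkl", win, g, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        w = self.weight.value
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, :, ki:ki + ho, kj:kj + wo] += np.einsum(
                    "ncdxy,cd->ncxy", g, w[:, :, ki, kj], optimize=True
                )
        pt, pb, pl, pr = self._pad
        h, w = dxp.shape[2], dxp.shape[3]
        return dxp[:, :, pt:h - pb or None, pl:w - pr or None]


class BatchNorm2d(Module):
    """Per-channel batch normalization over (batch, height, width).

    Learned affine scale/shift are the only trainable values (2 per channel);
    running statistics are buffers and never counted as parameters.
    """

    def __init__(self, num_features: int, *, eps: float = 1e-5, momentum: float = 0.1,
                 affine: bool = True, name: str = "bn"):
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.affine = affine
        if affine:
            self.gamma = Parameter(f"{name}.weight", np.ones(num_features))
            self.beta = Parameter(f"{name}.bias", np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta] if self.affine else []

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        if self.affine:
            return xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        return xhat

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        if self.affine:
            self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += grad.sum(axis=(0, 2, 3))
            dxhat = grad * self.gamma.value[None, :, None, None]
        else:
            dxhat = grad
        if not self.training:
            return dxhat * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True).reshape(1, -1, 1, 1)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True).reshape(1, -1, 1, 1)
        return (inv[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class AvgPool2d(Module):
    def __init__(self, kernel_size: tuple[int, int], stride: tuple[int, int] | None = None):
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel_size
        sh, sw = self.stride
        self._in_shape = x.shape
        win = _windows(x, kh, kw)[:, :, ::sh, ::sw]
        self._out_hw = win.shape[2], win.shape[3]
        return win.mean(axis=(4, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel_size
        sh, sw = self.stride
        dx = np.zeros(self._in_shape)
        g = grad / (kh * kw)
        ho, wo = self._out_hw
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i:i + ho * sh:sh, j:j + wo * sw:sw] += g
        return dx


class MaxPool2d(Module):
    def __init__(self, kernel_size: tuple[int, int], stride: tuple[int, int] | None = None):
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel_size
        sh, sw = self.stride
        self._in_shape = x.shape
        win = _windows(x, kh, kw)[:, :, ::sh, ::sw]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, kh * kw)
        self._argmax = flat.argmax(axis=4)
        self._out_hw = (ho, wo)
        return flat.max(axis=4)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel_size
        sh, sw = self.stride
        n, c, h, w = self._in_shape
        ho, wo = self._out_hw
        dx = np.zeros(self._in_shape)
        ki, kj = np.divmod(self._argmax, kw)
        ii = ki + np.arange(ho)[None, None, :, None] * sh
        jj = kj + np.arange(wo)[None, None, None, :] * sw
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dx, (nn, cc, ii, jj), grad)
        return dx


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.alpha * np.expm1(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        return grad * np.where(x > 0, 1.0, self.alpha * np.exp(x))


class Square(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x * x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * 2.0 * self._x


class SafeLog(Module):
    """log(max(x, eps)) — the logarithmic nonlinearity after squared pooling."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xc = np.maximum(x, self.eps)
        self._mask = x > self.eps
        return np.log(self._xc)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask / self._xc


class Identity(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(f"{name}.weight",
                                uniform_fan_in(rng, (out_features, in_features), in_features))
        self.bias = Parameter(f"{name}.bias",
                              uniform_fan_in(rng, (out_features,), in_features)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class CrossEntropyLoss:
    """Softmax cross-entropy on raw logits, mean over the batch."""

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        self._p = np.exp(logp)
        self._labels = labels
        return float(-logp[np.arange(len(labels)), labels].mean())

    def backward(self) -> np.ndarray:
        n = len(self._labels)
        g = self._p.copy()
        g[np.arange(n), self._labels] -= 1.0
        return g / n

    __call__ = forward


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params: Sequence[Parameter], *, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
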