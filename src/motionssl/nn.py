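"""Neural-network building blocks on the package's autograd engine.

Layers follow the conventional shapes: ``Linear`` acts on the last axis,
``Conv1d`` on (n, channels, time), ``Conv2d`` on (n, channels, H, W),
attention on (n, time, model_dim).  Every layer takes a
``numpy.random.Generator`` at construction so weight initialisation is a
pure function of the seed.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .autograd import Parameter, Tensor, concatenate, conv2d, norm_affine

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "Conv2d",
    "BatchNorm",
    "LayerNorm",
    "ReLU",
    "Sequential",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "sinusoidal_positions",
    "softmax",
    "cross_entropy",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, p in params.items():
            if k not in state:
                raise KeyError(f"missing parameter '{k}' in state dict")
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for '{k}'")
            p.data = np.array(state[k], dtype=np.float64)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = np.array(state[f"__bn{i}.running_mean"])
                m.running_var = np.array(state[f"__bn{i}.running_var"])

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = math.sqrt(2.0 / in_dim)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: tuple[int, int],
        rng: np.random.Generator,
        stride: tuple[int, int] = (1, 1),
        padding: tuple[int, int] | str = "same",
    ):
        super().__init__()
        kh, kw = kernel_size
        if padding == "same":
            padding = (kh // 2, kw // 2)
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kh * kw
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_channels, in_channels, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Conv1d(Module):
    """Temporal convolution on (n, channels, T), backed by Conv2d."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | str = "same",
    ):
        super().__init__()
        if padding == "same":
            padding = kernel_size // 2
        self._conv = Conv2d(
            in_channels,
            out_channels,
            (kernel_size, 1),
            rng,
            stride=(stride, 1),
            padding=(padding, 0),
        )

    def forward(self, x: Tensor) -> Tensor:
        n, c, t = x.shape
        out = self._conv(x.reshape(n, c, t, 1))
        return out.reshape(out.shape[0], out.shape[1], out.shape[2])


class BatchNorm(Module):
    """Batch normalisation over all axes except the channel axis (axis 1,
    or the last axis for 2-D inputs)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _axes_and_shape(self, x: Tensor):
        if x.ndim == 2:
            axes = (0,)
            shape = (1, -1)
        else:
            axes = (0,) + tuple(range(2, x.ndim))
            shape = (1, -1) + (1,) * (x.ndim - 2)
        return axes, shape

    def forward(self, x: Tensor) -> Tensor:
        axes, shape = self._axes_and_shape(x)
        w = self.weight.reshape(shape)
        b = self.bias.reshape(shape)
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.reshape(-1)
            return norm_affine(x, w, b, axes, self.eps)
        running = (self.running_mean.reshape(shape), self.running_var.reshape(shape))
        return norm_affine(x, w, b, axes, self.eps, running=running)


class LayerNorm(Module):
    """Normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return norm_affine(x, self.weight, self.bias, (-1,), self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    n, k = logits.shape
    shifted = logits - Tensor(np.max(logits.data, axis=1, keepdims=True))
    logz = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - logz
    onehot = np.zeros((n, k))
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional signal, shape (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class MultiHeadSelfAttention(Module):
    def __init__(self, model_dim: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if model_dim % num_heads != 0:
            raise ValueError("model_dim must be divisible by num_heads")
        self.num_heads = num_heads
        self.head_dim = model_dim // num_heads
        self.qkv = Linear(model_dim, 3 * model_dim, rng)
        self.out = Linear(model_dim, model_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, hd = self.num_heads, self.head_dim
        qkv = self.qkv(x).reshape(n, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (n, h, t, hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm residual block: x + MHSA(LN(x)), then x + FFN(LN(x)).

    With the residual path outside the normalisation, zeroing a sub-layer's
    output projection makes the block an exact identity.
    """

    def __init__(self, model_dim: int, num_heads: int, rng: np.random.Generator, ffn_mult: int = 2):
        super().__init__()
        self.ln1 = LayerNorm(model_dim)
        self.attn = MultiHeadSelfAttention(model_dim, num_heads, rng)
        self.ln2 = LayerNorm(model_dim)
        self.ffn = Sequential(
            Linear(model_dim, ffn_mult * model_dim, rng),
            ReLU(),
            Linear(ffn_mult * model_dim, model_dim, rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        x = x + self.ffn(self.ln2(x))
        return x
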