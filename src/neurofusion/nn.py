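"""Small neural-network layer library on top of :mod:`neurofusion.autodiff`.

Layers hold their parameters as :class:`~neurofusion.autodiff.Tensor` objects
and expose ``parameters()`` for the optimizer.  Initialization is driven by an
explicit ``numpy.random.Generator`` so every model build is reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, softmax, zero_pad

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "MultiHeadAttention",
    "TransformerLayer",
    "Adam",
]


class Module:
    """Base class: recursively collects Tensor parameters from attributes."""

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for value in vars(self).values():
            yield from _params_of(value, seen)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        seen: set[int] = set()
        for name, value in vars(self).items():
            yield from _named_params_of(value, f"{prefix}{name}", seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _params_of(value, seen: set[int]):
    if isinstance(value, Tensor):
        if value.requires_grad and id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for p in value.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _params_of(item, seen)


def _named_params_of(value, name: str, seen: set[int]):
    if isinstance(value, Tensor):
        if value.requires_grad and id(value) not in seen:
            seen.add(id(value))
            yield name, value
    elif isinstance(value, Module):
        for sub, p in value.named_parameters(prefix=name + "."):
            if id(p) not in seen:
                seen.add(id(p))
                yield sub, p
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _named_params_of(item, f"{name}.{i}", seen)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.shift = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gain + self.shift


def _im2col_indices(h: int, w: int, k: int, stride: int, pad: int):
    """Row/col gather indices for a k x k convolution on a padded image."""
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    r0 = np.repeat(np.arange(out_h) * stride, out_w)
    c0 = np.tile(np.arange(out_w) * stride, out_h)
    dr = np.repeat(np.arange(k), k)
    dc = np.tile(np.arange(k), k)
    rows = r0[:, None] + dr[None, :]          # (out_h*out_w, k*k)
    cols = c0[:, None] + dc[None, :]
    return rows, cols, out_h, out_w


class Conv2d(Module):
    """2D convolution (im2col + matmul) over NHWC inputs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        fan_in = kernel * kernel * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(fan_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        self._idx_cache: dict[tuple[int, int], tuple] = {}

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        k = self.kernel
        if k == self.stride and self.pad == 0 and h % k == 0 and w % k == 0:
            # non-overlapping patchify: pure reshape/transpose im2col
            oh, ow = h // k, w // k
            patches = (x.reshape(b, oh, k, ow, k, c)
                        .transpose((0, 1, 3, 2, 4, 5))
                        .reshape(b, oh * ow, k * k * c))
            out = patches @ self.weight + self.bias
            return out.reshape(b, oh, ow, -1)
        key = (h, w)
        if key not in self._idx_cache:
            self._idx_cache[key] = _im2col_indices(h, w, k, self.stride,
                                                   self.pad)
        rows, cols, out_h, out_w = self._idx_cache[key]
        if self.pad:
            x = _pad_hw(x, self.pad)
        patches = x[:, rows, cols, :]          # (b, out_h*out_w, k*k, c)
        patches = patches.reshape(b, out_h * out_w, k * k * c)
        out = patches @ self.weight + self.bias
        return out.reshape(b, out_h, out_w, -1)


def _pad_hw(x: Tensor, pad: int) -> Tensor:
    return zero_pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))


class MultiHeadAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"model dim {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.out_proj = Linear(d, d, rng)

    def __call__(self, x: Tensor, mask_bias: np.ndarray | None = None) -> Tensor:
        """x: (..., L, d); mask_bias broadcastable to (..., L, L), additive."""
        *lead, L, d = x.shape
        def split(t: Tensor) -> Tensor:
            t = t.reshape(*lead, L, self.n_heads, self.d_head)
            return t.swapaxes(-2, -3)          # (..., heads, L, d_head)
        q = split(self.q_proj(x))
        k = split(self.k_proj(x))
        v = split(self.v_proj(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        if mask_bias is not None:
            scores = scores + Tensor(mask_bias)
        attn = softmax(scores, axis=-1)
        out = attn @ v                          # (..., heads, L, d_head)
        out = out.swapaxes(-2, -3).reshape(*lead, L, d)
        return self.out_proj(out)


class TransformerLayer(Module):
    """Pre-norm self-attention + GELU feed-forward block."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 4):
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.norm2 = LayerNorm(d)
        self.ff1 = Linear(d, ff_mult * d, rng)
        self.ff2 = Linear(ff_mult * d, d, rng)

    def __call__(self, x: Tensor, mask_bias: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), mask_bias=mask_bias)
        return x + self.ff2(self.ff1(self.norm2(x)).gelu())


class Adam:
    """Adam optimizer with the standard moment defaults."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
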