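"""Network building blocks (linear, layer-norm, multi-head attention) and a
numpy Adam optimizer, built on the :mod:`spinereg.nn.autodiff` tensors.

Parameters are named ``Tensor`` leaves collected recursively through module
attributes, so a whole model serializes as a flat ``{name: array}`` dict.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concatenate


class Module:
    """Base class: collects parameter tensors from attributes recursively."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Linear(Module):
    """Affine map on the last axis; Kaiming-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Shared (point-wise) multi-layer perceptron with ReLU between layers.

    ``relu_last`` controls whether the final layer is also activated.
    """

    def __init__(self, widths: list[int], rng: np.random.Generator, relu_last: bool = True):
        if len(widths) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.relu_last = relu_last

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.relu_last:
                x = x.relu()
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention of queries ``x`` over context ``ctx``."""

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        if dim % num_heads != 0:
            raise ValueError(f"feature dim {dim} not divisible by {num_heads} heads")
        self.dim = dim
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, t: Tensor, n: int) -> Tensor:
        # (n, dim) -> (heads, n, head_dim)
        return t.reshape(n, self.num_heads, self.head_dim).transpose(1, 0, 2)

    def __call__(self, x: Tensor, ctx: Tensor) -> Tensor:
        n, m = x.shape[0], ctx.shape[0]
        q = self._split(self.wq(x), n)
        k = self._split(self.wk(ctx), m)
        v = self._split(self.wv(ctx), m)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(1, 0, 2).reshape(n, self.dim)
        return self.wo(out)


class AttentionBlock(Module):
    """Attention + residual + LN, then a 2-layer feed-forward + residual + LN."""

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, num_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ffn = MLP([dim, 2 * dim, dim], rng, relu_last=False)
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor, ctx: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x, ctx))
        return self.norm2(x + self.ffn(x))


class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


__all__ = ["Module", "Linear", "MLP", "LayerNorm", "MultiHeadAttention",
           "AttentionBlock", "Adam", "Tensor", "concatenate"]
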