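"""Neural building blocks: linear/layer-norm layers, masked multi-head
self-attention, pre-norm transformer blocks, a miniature residual CNN and an
Adam optimizer.  All parameters are float64 :class:`~longict.nn.autodiff.Tensor`s.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, softmax

NEG_INF = -np.inf


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        out, seen = [], set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    if not k.startswith("last_"):   # runtime caches, not params
                        walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, arr in zip(params, state):
            p.data[...] = np.asarray(arr, dtype=float).reshape(p.data.shape)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Tensor(_kaiming(rng, d_in, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.b


class MultiHeadSelfAttention(Module):
    """Self-attention over the second-to-last axis with key masking.

    Invalid keys receive an additive ``-inf`` logit, hence exactly zero
    attention weight after the softmax.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("embedding dim must be divisible by head count")
        self.d, self.h = d, n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        *lead, t, d = x.shape
        hd = d // self.h

        def split(z: Tensor) -> Tensor:
            # (..., T, d) -> (..., h, T, hd)
            return z.reshape(*lead, t, self.h, hd).swapaxes(-2, -3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = (q @ k.swapaxes(-1, -2)) * (hd ** -0.5)   # (..., h, T, T)
        bias = np.where(np.asarray(key_mask, bool), 0.0, NEG_INF)
        logits = logits + Tensor(bias[..., None, None, :])
        attn = softmax(logits, axis=-1)
        self.last_attention = attn.data
        out = (attn @ v).swapaxes(-2, -3).reshape(*lead, t, d)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MHA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, d_ff, rng)
        self.fc2 = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), key_mask)
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


class TransformerEncoder(Module):
    def __init__(self, d: int, n_heads: int, n_layers: int, rng: np.random.Generator,
                 d_ff: int | None = None):
        d_ff = d_ff or 2 * d
        self.blocks = [TransformerBlock(d, n_heads, d_ff, rng) for _ in range(n_layers)]

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        for blk in self.blocks:
            x = blk(x, key_mask)
        return x

    @property
    def last_attention(self) -> np.ndarray:
        return self.blocks[-1].attn.last_attention


class ResidualBlock(Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        k = 3
        self.w1 = Tensor(_kaiming(rng, c_in * k * k, (c_out, c_in, k, k)), requires_grad=True)
        self.b1 = Tensor(np.zeros(c_out), requires_grad=True)
        self.w2 = Tensor(_kaiming(rng, c_out * k * k, (c_out, c_out, k, k)), requires_grad=True)
        self.b2 = Tensor(np.zeros(c_out), requires_grad=True)
        self.proj = None
        if stride != 1 or c_in != c_out:
            self.proj = Tensor(_kaiming(rng, c_in, (c_out, c_in, 1, 1)), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        h = conv2d(x, self.w1, self.b1, stride=self.stride, padding=1).relu()
        h = conv2d(h, self.w2, self.b2, stride=1, padding=1)
        skip = x if self.proj is None else conv2d(x, self.proj, stride=self.stride)
        return (h + skip).relu()


class MiniResNet(Module):
    """ResNet-style feature extractor in miniature.

    A strided stem followed by downsampling residual stages and global average
    pooling, projecting a 3-channel patch to a ``d``-dimensional embedding.
    Channel widths scale with ``width``; depth is fixed at one block per stage.
    """

    def __init__(self, d_out: int, rng: np.random.Generator,
                 width: int = 8, n_stages: int = 3):
        c = width
        self.stem_w = Tensor(_kaiming(rng, 3 * 9, (c, 3, 3, 3)), requires_grad=True)
        self.stem_b = Tensor(np.zeros(c), requires_grad=True)
        self.stages = []
        for _ in range(n_stages):
            self.stages.append(ResidualBlock(c, 2 * c, stride=2, rng=rng))
            c *= 2
        self.head = Linear(c, d_out, rng)
        self.last_conv_activations: Tensor | None = None

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, 3, H, W) -> (N, d_out)."""
        h = conv2d(x, self.stem_w, self.stem_b, stride=2, padding=1).relu()
        for stage in self.stages:
            h = stage(h)
        self.last_conv_activations = h          # kept for GradCAM
        pooled = h.mean(axis=(-1, -2))
        return self.head(pooled)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
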