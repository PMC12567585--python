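"""Neural-network building blocks (Linear, LayerNorm, attention, ViT, BiLSTM).

All layers hold their parameters as :class:`~actifuse.autodiff.Tensor` leaves
and are pure-numpy; sized for the CPU-scale presets this package trains.
Initialisation draws from a ``numpy.random.Generator`` passed in explicitly so
every model build is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, layernorm, stack

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "Mlp",
    "MultiHeadSelfAttention", "TransformerBlock", "VisionTransformer", "BiLstm",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialisation."""

    training: bool = True

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _walk_modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value._walk_modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item._walk_modules()

    def train(self):
        for m in self._walk_modules():
            m.training = True
        return self

    def eval(self):
        for m in self._walk_modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform(rng, fan_in, shape):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_uniform(rng, in_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layernorm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask noise comes from `rng`."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(self.fc1(x).gelu())


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        h, dh = self.heads, self.dim // self.heads
        qkv = self.qkv(x).reshape(B, N, 3, h, dh).transpose(2, 0, 3, 1, 4)  # 3,B,h,N,dh
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = ((q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(dh))).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class VisionTransformer(Module):
    """Patch-embedding transformer encoder; returns the final-layer class token.

    The classification head is deliberately absent: this module is a feature
    extractor producing one `embed_dim` vector per image.
    """

    def __init__(self, image_size: int, patch_size: int, depth: int, heads: int,
                 embed_dim: int, rng: np.random.Generator, in_channels: int = 3,
                 mlp_ratio: float = 4.0):
        if image_size % patch_size:
            raise ValueError(f"image size {image_size} not divisible by patch size {patch_size}")
        self.image_size = image_size
        self.patch_size = patch_size
        self.in_channels = in_channels
        n_patches = (image_size // patch_size) ** 2
        patch_dim = in_channels * patch_size * patch_size
        self.patch_proj = Linear(patch_dim, embed_dim, rng)
        self.cls_token = Tensor(rng.normal(0, 0.02, (1, 1, embed_dim)), requires_grad=True)
        self.pos_embed = Tensor(rng.normal(0, 0.02, (1, n_patches + 1, embed_dim)), requires_grad=True)
        self.blocks = [TransformerBlock(embed_dim, heads, mlp_ratio, rng) for _ in range(depth)]
        self.norm = LayerNorm(embed_dim)

    def _to_patches(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        ps = self.patch_size
        x = x.reshape(B, C, H // ps, ps, W // ps, ps)
        x = x.transpose(0, 2, 4, 1, 3, 5)  # B, gh, gw, C, ps, ps
        return x.reshape(B, (H // ps) * (W // ps), C * ps * ps)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if (C, H, W) != (self.in_channels, self.image_size, self.image_size):
            raise ValueError(
                f"expected input of shape (B, {self.in_channels}, {self.image_size}, "
                f"{self.image_size}), got {tuple(x.shape)}")
        tok = self.patch_proj(self._to_patches(x))
        cls = Tensor(np.ones((B, 1, 1))) * self.cls_token  # broadcast copy per sample
        tok = concat([cls, tok], axis=1) + self.pos_embed
        for blk in self.blocks:
            tok = blk(tok)
        return self.norm(tok)[:, 0, :]


class _LstmDirection(Module):
    def __init__(self, in_dim: int, hidden: int, rng):
        self.hidden = hidden
        self.wx = Linear(in_dim, 4 * hidden, rng)
        self.wh = Linear(hidden, 4 * hidden, rng, bias=False)

    def forward(self, xs):
        """xs: list of (B, in_dim) tensors in processing order; returns list of h_t."""
        B = xs[0].shape[0]
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for x in xs:
            gates = self.wx(x) + self.wh(h)
            i = gates[:, 0 * H:1 * H].sigmoid()
            f = gates[:, 1 * H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs


class BiLstm(Module):
    """Stacked bidirectional LSTM over short frame-embedding sequences.

    `forward` returns per-frame tokens of width ``2 * hidden`` plus the pooled
    sequence vector (last forward state concatenated with last backward state),
    matching the two consumers downstream: attention K/V tokens and the
    late-fusion baselines.
    """

    def __init__(self, input_dim: int, hidden: int, layers: int, rng):
        if layers < 1:
            raise ValueError("BiLstm needs at least one layer")
        self.hidden = hidden
        self.fwd = []
        self.bwd = []
        d = input_dim
        for _ in range(layers):
            self.fwd.append(_LstmDirection(d, hidden, rng))
            self.bwd.append(_LstmDirection(d, hidden, rng))
            d = 2 * hidden

    def forward(self, x: Tensor):
        B, T, D = x.shape
        if T < 1:
            raise ValueError("empty frame sequence")
        xs = [x[:, t, :] for t in range(T)]
        for fwd, bwd in zip(self.fwd, self.bwd):
            hf = fwd(xs)
            hb = bwd(xs[::-1])[::-1]
            xs = [concat([f, b], axis=1) for f, b in zip(hf, hb)]
            last_f, last_b = hf[-1], hb[0]
        tokens = stack(xs, axis=1)          # (B, T, 2H)
        pooled = concat([last_f, last_b], axis=1)  # (B, 2H)
        return tokens, pooled
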