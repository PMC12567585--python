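"""Multimodal network: ViT frame encoder, BiLSTM temporal aggregator, and four
fusion strategies over image and clinical-tabular representations.

Per sample the image branch consumes a sequence of five 3-channel GAF frames.
Each frame is encoded by a Vision Transformer (classification head removed,
final-layer class token kept), the per-frame embeddings are aggregated by a
stacked bidirectional LSTM yielding (a) one token per frame and (b) a pooled
sequence vector. The clinical vector is fused with the image branch by one of:

``cross_attention``
    The tabular vector is projected to a single query; the five BiLSTM frame
    tokens are projected to keys and values; scaled dot-product attention
    (optionally multi-head) produces the fused vector
    ``softmax(Q K^T / sqrt(d_k)) V``. A ``single_token`` compatibility mode
    collapses the K/V set to the pooled sequence vector, in which case the
    softmax is over a singleton and the fusion returns V exactly.
``simple_concat``
    Concatenation of tabular vector and pooled image vector, then a linear
    map to the fused dimension.
``weighted_sum``
    Both modalities projected to the fused dimension and mixed by a learnable
    scalar gate through a sigmoid.
``dual_stream``
    Two independent MLP heads produce per-modality class logits; the final
    logits are their unweighted mean.

The classifier head applies dropout (training mode only) and a linear map from
the fused dimension to the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat
from .nn import BiLstm, Dropout, Linear, Module, VisionTransformer

__all__ = ["ViTConfig", "BiLstmConfig", "FusionConfig", "FUSION_KINDS",
           "MultimodalNet", "cross_attention_fuse"]

FUSION_KINDS = ("cross_attention", "simple_concat", "weighted_sum", "dual_stream")


@dataclass
class ViTConfig:
    image_size: int = 224
    patch_size: int = 16
    depth: int = 12
    heads: int = 12
    embed_dim: int = 768
    pretrained: bool = False
    weights_path: str = None

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.pretrained and not self.weights_path:
            raise ValueError("pretrained=True requires weights_path (no weights are bundled)")

    @classmethod
    def tiny(cls):
        """CPU-scale preset used throughout the tests."""
        return cls(image_size=32, patch_size=8, depth=2, heads=4, embed_dim=64)


@dataclass
class BiLstmConfig:
    input_dim: int = 768
    hidden: int = 128
    layers: int = 2

    @property
    def token_dim(self) -> int:
        return 2 * self.hidden

    @classmethod
    def tiny(cls):
        return cls(input_dim=64, hidden=32, layers=1)


@dataclass
class FusionConfig:
    kind: str = "cross_attention"
    d_k: int = 128
    heads: int = 4
    dropout: float = 0.5
    single_token: bool = False

    def __post_init__(self):
        if self.kind not in FUSION_KINDS:
            raise ValueError(f"unknown fusion kind {self.kind!r}; choose from {FUSION_KINDS}")
        if self.d_k % self.heads:
            raise ValueError("d_k must be divisible by fusion heads")

    @classmethod
    def tiny(cls, kind="cross_attention"):
        return cls(kind=kind, d_k=32, heads=2)


def cross_attention_fuse(q: Tensor, k: Tensor, v: Tensor, heads: int = 1):
    """Scaled dot-product cross attention, tabular query over image tokens.

    q: (B, 1, d_k); k, v: (B, T, d_k). With multiple heads, d_k is split per
    head and the attended heads are concatenated back (no output projection, so
    a singleton token set returns V exactly in every head configuration).
    Returns (fused (B, d_k), attention weights (B, heads, 1, T)).
    """
    B, _, d_k = q.shape
    T = k.shape[1]
    dh = d_k // heads
    qh = q.reshape(B, 1, heads, dh).transpose(0, 2, 1, 3)
    kh = k.reshape(B, T, heads, dh).transpose(0, 2, 1, 3)
    vh = v.reshape(B, T, heads, dh).transpose(0, 2, 1, 3)
    attn = ((qh @ kh.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(dh))).softmax(axis=-1)
    fused = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, d_k)
    return fused, attn


class MultimodalNet(Module):
    """End-to-end classifier over (image sequence, tabular vector) pairs."""

    def __init__(self, vit_cfg: ViTConfig, lstm_cfg: BiLstmConfig,
                 fusion_cfg: FusionConfig, tabular_dim: int, seed: int = 42):
        if lstm_cfg.input_dim != vit_cfg.embed_dim:
            raise ValueError(
                f"BiLSTM input_dim {lstm_cfg.input_dim} must equal ViT embed_dim "
                f"{vit_cfg.embed_dim}")
        self.vit_cfg = vit_cfg
        self.lstm_cfg = lstm_cfg
        self.fusion_cfg = fusion_cfg
        self.tabular_dim = tabular_dim
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1,)))

        self.vit = VisionTransformer(vit_cfg.image_size, vit_cfg.patch_size,
                                     vit_cfg.depth, vit_cfg.heads, vit_cfg.embed_dim, rng)
        if vit_cfg.pretrained:
            state = np.load(vit_cfg.weights_path)
            self.vit.load_state_dict({k: state[k] for k in state.files})
        self.lstm = BiLstm(vit_cfg.embed_dim, lstm_cfg.hidden, lstm_cfg.layers, rng)

        tok = lstm_cfg.token_dim
        d_k = fusion_cfg.d_k
        kind = fusion_cfg.kind
        if kind == "cross_attention":
            self.w_q = Linear(tabular_dim, d_k, rng)
            self.w_k = Linear(tok, d_k, rng)
            self.w_v = Linear(tok, d_k, rng)
        elif kind == "simple_concat":
            self.fuse_proj = Linear(tabular_dim + tok, d_k, rng)
        elif kind == "weighted_sum":
            self.proj_tab = Linear(tabular_dim, d_k, rng)
            self.proj_img = Linear(tok, d_k, rng)
            self.alpha = Tensor(np.zeros(1), requires_grad=True)
        else:  # dual_stream
            self.tab_head = _MlpHead(tabular_dim, d_k, rng)
            self.img_head = _MlpHead(tok, d_k, rng)
        if kind != "dual_stream":
            self.drop = Dropout(fusion_cfg.dropout, self.dropout_rng)
            self.classifier = Linear(d_k, 2, rng)
        self.last_attention_ = None

    # ------------------------------------------------------------------ parts
    def encode_images(self, frames: Tensor):
        """frames: (B, F, C, H, W) -> per-frame embeddings (B, F, embed_dim)."""
        B, F, C, H, W = frames.shape
        emb = self.vit(frames.reshape(B * F, C, H, W))
        return emb.reshape(B, F, self.vit_cfg.embed_dim)

    def fuse(self, tab: Tensor, tokens: Tensor, pooled: Tensor):
        cfg = self.fusion_cfg
        if cfg.kind == "cross_attention":
            kv_src = pooled.reshape(pooled.shape[0], 1, pooled.shape[1]) \
                if cfg.single_token else tokens
            q = self.w_q(tab).reshape(tab.shape[0], 1, cfg.d_k)
            k, v = self.w_k(kv_src), self.w_v(kv_src)
            fused, attn = cross_attention_fuse(q, k, v, heads=cfg.heads)
            self.last_attention_ = attn.data
            return fused
        if cfg.kind == "simple_concat":
            return self.fuse_proj(concat([tab, pooled], axis=1))
        if cfg.kind == "weighted_sum":
            gate = self.alpha.sigmoid()
            return gate * self.proj_tab(tab) + (1.0 - gate) * self.proj_img(pooled)
        raise RuntimeError("dual_stream fuses at the logit level; use forward()")

    def classify(self, fused: Tensor) -> Tensor:
        """Fused vector -> class logits (dropout active in training mode)."""
        return self.classifier(self.drop(fused))

    # ---------------------------------------------------------------- forward
    def forward(self, frames: Tensor, tab: Tensor) -> Tensor:
        """Returns class logits of shape (B, 2)."""
        emb = self.encode_images(frames)
        tokens, pooled = self.lstm(emb)
        if self.fusion_cfg.kind == "dual_stream":
            logits = (self.tab_head(tab) + self.img_head(pooled)) * 0.5
            self.last_attention_ = None
            return logits
        return self.classify(self.fuse(tab, tokens, pooled))

    def predict_proba(self, frames: Tensor, tab: Tensor) -> np.ndarray:
        self.eval()
        from .autodiff import no_grad
        with no_grad():
            return self.forward(Tensor(frames), Tensor(tab)).softmax(axis=-1).data


class _MlpHead(Module):
    """Per-modality classification head for the dual-stream baseline."""

    def __init__(self, in_dim: int, hidden: int, rng):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, 2, rng)

    def forward(self, x):
        return self.fc2(self.fc1(x).relu())
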