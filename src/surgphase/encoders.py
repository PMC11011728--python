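"""Convolution-free transformer encoder applied per modality.

Each encoder is a stack of post-norm transformer blocks (multi-head
self-attention + residual + layer norm, then a position-wise feed-forward
network + residual + layer norm) applied to an embedding sequence after
sinusoidal positional encodings are added.  The pooled output is the mean
over positions, matching the image tower's global-average convention.  A
single-tower variant concatenates the image and text sequences (image
positions first) and runs one shared encoder — the ablation architecture.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .exceptions import ConfigurationError


def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding.

    PE[pos, 2i] = sin(pos / 10000^(2i/d)), PE[pos, 2i+1] = cos(...).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if d_model % 2:
        raise ValueError(f"d_model must be even, got {d_model}")
    pos = np.arange(length)[:, None]
    i = np.arange(0, d_model, 2)[None, :]
    angle = pos / np.power(10000.0, i / d_model)
    pe = np.empty((length, d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


@dataclasses.dataclass
class EncoderConfig:
    """Transformer encoder sizes (12 layers at full scale, 2 at desk scale)."""

    n_layers: int = 12
    d_model: int = 768
    n_heads: int = 12
    d_ff: int = 3072
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ConfigurationError("n_layers must be >= 1")
        if self.d_model % self.n_heads:
            raise ConfigurationError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @classmethod
    def desk_preset(cls, seed: int = 0, **overrides) -> "EncoderConfig":
        kw = dict(n_layers=2, d_model=32, n_heads=4, d_ff=64, seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclasses.dataclass
class EncoderOutput:
    hidden_states: np.ndarray  # L x d_model
    pooled: np.ndarray  # d_model (mean over positions)


class MultiHeadSelfAttention(nn.Module):
    """Scaled-dot-product self-attention with learned Q/K/V/output maps."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ConfigurationError(
                f"d_model={d_model} not divisible by n_heads={n_heads}"
            )
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = nn.Linear(d_model, d_model, rng)
        self.wk = nn.Linear(d_model, d_model, rng)
        self.wv = nn.Linear(d_model, d_model, rng)
        self.wo = nn.Linear(d_model, d_model, rng)

    def attention_weights(self, x: np.ndarray, mask=None) -> np.ndarray:
        """(B, H, L, L) softmax attention matrix for inspection/testing."""
        out, attn = self._forward(nn.constant(np.asarray(x)), mask,
                                  return_attn=True)
        return attn

    def _forward(self, x: nn.Tensor, mask=None, return_attn=False):
        b, length, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t):
            return t.reshape((b, length, h, dh)).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        if mask is not None:
            scores = scores + nn.constant(mask)
        attn = nn.softmax(scores, axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape((b, length, d))
        out = self.wo(ctx)
        if return_attn:
            return out, attn.data
        return out

    def __call__(self, x: nn.Tensor, mask=None) -> nn.Tensor:
        return self._forward(x, mask)


class TransformerBlock(nn.Module):
    """Post-norm block: LN(x + MHSA(x)) then LN(h + FFN(h))."""

    def __init__(self, d_model, n_heads, d_ff, rng, dropout_rate=0.0, seed=0):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = nn.LayerNorm(d_model)
        self.fc1 = nn.Linear(d_model, d_ff, rng)
        self.fc2 = nn.Linear(d_ff, d_model, rng)
        self.ln2 = nn.LayerNorm(d_model)
        self.dropout_rate = dropout_rate
        self._drop_rng = np.random.default_rng(seed)
        self.training = False

    def _dropout(self, t: nn.Tensor) -> nn.Tensor:
        if not getattr(self, "training", False) or self.dropout_rate == 0.0:
            return t
        keep = 1.0 - self.dropout_rate
        mask = self._drop_rng.random(t.shape) < keep
        return t * nn.constant(mask / keep)

    def __call__(self, x: nn.Tensor, mask=None) -> nn.Tensor:
        h = self.ln1(x + self._dropout(self.attn(x, mask)))
        f = self.fc2(self.fc1(h).relu())
        return self.ln2(h + self._dropout(f))


def attention_mask(lengths: np.ndarray, max_len: int) -> np.ndarray:
    """Additive key mask (B, 1, 1, L): 0 for valid keys, -1e9 for padding."""
    lengths = np.asarray(lengths)
    valid = np.arange(max_len)[None, :] < lengths[:, None]
    return np.where(valid, 0.0, -1e9)[:, None, None, :]


class TransformerEncoder(nn.Module):
    """Stack of transformer blocks with positional encoding and mean pooling."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks = [
            TransformerBlock(
                config.d_model, config.n_heads, config.d_ff, rng,
                dropout_rate=config.dropout_rate, seed=config.seed + 7 * i,
            )
            for i in range(config.n_layers)
        ]
        self.training = False

    def forward(self, x: nn.Tensor, mask=None) -> nn.Tensor:
        """Batched forward: Tensor (B, L, d_model) -> Tensor (B, L, d_model)."""
        b, length, d = x.shape
        x = x + nn.constant(positional_encoding(length, d))
        for blk in self.blocks:
            x = blk(x, mask)
        return x

    def encode(self, seq) -> EncoderOutput:
        """Encode one L x d_model sequence (array or EmbeddingSequence)."""
        vectors = np.asarray(getattr(seq, "vectors", seq), dtype=np.float64)
        if not np.isfinite(vectors).all():
            raise FloatingPointError("encoder input contains non-finite values")
        if vectors.shape[-1] != self.config.d_model:
            raise ConfigurationError(
                f"sequence dim {vectors.shape[-1]} != d_model "
                f"{self.config.d_model}"
            )
        out = self.forward(nn.constant(vectors[None])).data[0]
        return EncoderOutput(hidden_states=out, pooled=out.mean(axis=0))


def masked_mean(h: nn.Tensor, lengths: np.ndarray | None = None) -> nn.Tensor:
    """Mean over the sequence axis, ignoring padded positions."""
    b, length, d = h.shape
    if lengths is None:
        return h.mean(axis=1)
    lengths = np.asarray(lengths, dtype=np.float64)
    valid = (np.arange(length)[None, :] < lengths[:, None]).astype(np.float64)
    summed = (h * nn.constant(valid[..., None])).sum(axis=1)
    return summed * nn.constant(1.0 / lengths[:, None])


def single_tower_forward(img_seq, txt_seq, encoder: TransformerEncoder):
    """Ablation forward: concatenate sequences (image first), encode, pool."""
    img = np.asarray(getattr(img_seq, "vectors", img_seq), dtype=np.float64)
    txt = np.asarray(getattr(txt_seq, "vectors", txt_seq), dtype=np.float64)
    if img.shape[-1] != txt.shape[-1]:
        raise ConfigurationError(
            f"modality dims differ: {img.shape[-1]} vs {txt.shape[-1]}"
        )
    return encoder.encode(np.concatenate([img, txt], axis=0)).pooled
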