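"""Modality-specific embedding towers.

The image tower is ViT-style: the frame is cut into non-overlapping patches,
each patch is linearly projected, sinusoidal positional encodings are added
and a small stack of transformer blocks refines the patch sequence; global
average pooling over patches yields a fixed-size frame vector.  The text
tower maps whitespace tokens to learned embedding rows plus positional
encodings.  Both towers are trainable from scratch; externally precomputed
embedding tables (e.g. from large pretrained vision/language models) can be
imported through :func:`load_precomputed_embeddings` and used in their place.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np

from . import nn
from .encoders import TransformerBlock, positional_encoding
from .exceptions import ConfigurationError, DimensionError, FormatError

PAD_ID = 0
UNK_ID = 1


@dataclasses.dataclass
class EmbeddingSequence:
    """L x D sequence of feature vectors for one modality."""

    vectors: np.ndarray
    modality: str  # "image" | "text"
    source_id: object = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise DimensionError("vectors must be a non-empty L x D matrix")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding sequence contains non-finite entries")


@dataclasses.dataclass
class TowerConfig:
    """Sizes of one embedding tower.

    The full-scale defaults mirror a ViT-B/16-class tower (768-D output,
    16-pixel patches); `desk_preset` is the small configuration used for
    CPU-scale training and testing.
    """

    d_out: int = 768
    patch_size: int = 16
    n_blocks: int = 12
    n_heads: int = 12
    d_ff: int = 3072
    vocab_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.d_out % self.n_heads:
            raise ConfigurationError(
                f"d_out={self.d_out} not divisible by n_heads={self.n_heads}"
            )
        if self.patch_size < 1:
            raise ConfigurationError("patch_size must be >= 1")

    @classmethod
    def desk_preset(cls, seed: int = 0, **overrides) -> "TowerConfig":
        kw = dict(
            d_out=32, patch_size=16, n_blocks=1, n_heads=4, d_ff=64,
            vocab_size=256, seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


# ----------------------------------------------------------------- patchify
def patchify(frame: np.ndarray, patch_size: int) -> np.ndarray:
    """Cut an H x W x C frame into row-major (H/P)(W/P) patch vectors.

    Each row of the result is one flattened P x P x C patch; concatenating
    all rows is a permutation of the input pixels.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = frame[..., None]
    h, w, c = frame.shape
    p = patch_size
    if h % p:
        raise DimensionError(f"height {h} not divisible by patch size {p}")
    if w % p:
        raise DimensionError(f"width {w} not divisible by patch size {p}")
    patches = frame.reshape(h // p, p, w // p, p, c).transpose(0, 2, 1, 3, 4)
    return patches.reshape((h // p) * (w // p), p * p * c)


def unpatchify(patches: np.ndarray, h: int, w: int, c: int, patch_size: int):
    """Inverse of :func:`patchify`."""
    p = patch_size
    arr = patches.reshape(h // p, w // p, p, p, c).transpose(0, 2, 1, 3, 4)
    return arr.reshape(h, w, c)


def _patchify_batch(frames: np.ndarray, patch_size: int) -> np.ndarray:
    b, h, w, c = frames.shape
    p = patch_size
    if h % p or w % p:
        raise DimensionError("frame not divisible by patch size")
    patches = frames.reshape(b, h // p, p, w // p, p, c).transpose(
        0, 1, 3, 2, 4, 5
    )
    return patches.reshape(b, (h // p) * (w // p), p * p * c)


# ------------------------------------------------------------------- towers
class ImageTower(nn.Module):
    """Patch projection + transformer blocks + global average pooling."""

    def __init__(self, config: TowerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        p = config.patch_size
        self.proj = nn.Linear(p * p * 3, config.d_out, rng)
        self.blocks = [
            TransformerBlock(config.d_out, config.n_heads, config.d_ff, rng)
            for _ in range(config.n_blocks)
        ]
        self.training = False

    def forward(self, frames: np.ndarray) -> nn.Tensor:
        """Batched forward: (B, H, W, C) -> Tensor (B, N_patches, d_out)."""
        patches = _patchify_batch(np.asarray(frames, dtype=np.float64),
                                  self.config.patch_size)
        # embeddings scaled by sqrt(d) before the positional encoding is
        # added, per the original transformer convention, so the content
        # signal is not swamped by the shared positional component
        x = self.proj(nn.constant(patches)) * np.sqrt(self.config.d_out)
        x = x + nn.constant(positional_encoding(patches.shape[1],
                                                self.config.d_out))
        for blk in self.blocks:
            x = blk(x)
        return x

    def sequence(self, frame: np.ndarray) -> EmbeddingSequence:
        out = self.forward(np.asarray(frame)[None])
        return EmbeddingSequence(out.data[0], modality="image")

    def embed(self, frame: np.ndarray) -> np.ndarray:
        """Pooled frame vector (global average over the patch sequence)."""
        return self.forward(np.asarray(frame)[None]).data[0].mean(axis=0)


def embed_image(frame: np.ndarray, tower: ImageTower) -> np.ndarray:
    return tower.embed(frame)


# --------------------------------------------------------------------- text
def build_vocab(corpus, min_count: int = 1) -> dict:
    """Whitespace/lowercase frequency vocabulary with PAD=0 and UNK=1.

    Tokens are ordered by (frequency desc, token asc), so rebuilding on the
    same corpus yields the identical mapping.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    counts: dict = {}
    for line in corpus:
        for tok in line.lower().split():
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    vocab = {"<pad>": PAD_ID, "<unk>": UNK_ID}
    for i, tok in enumerate(kept):
        vocab[tok] = i + 2
    return vocab


def tokenize(text: str, vocab: dict) -> list:
    """Token ids for a text; empty text maps to a single padding token."""
    toks = text.lower().split()
    if not toks:
        return [PAD_ID]
    return [vocab.get(t, UNK_ID) for t in toks]


class TextTower(nn.Module):
    """Learned token-embedding table plus positional encoding."""

    def __init__(self, config: TowerConfig, vocab: dict):
        if len(vocab) > config.vocab_size:
            raise ConfigurationError(
                f"vocab has {len(vocab)} entries but config.vocab_size is "
                f"{config.vocab_size}"
            )
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed + 1)
        self.table = nn.Parameter(
            nn.init_uniform(rng, (config.vocab_size, config.d_out), config.d_out)
        )
        self.training = False

    def forward(self, ids: np.ndarray) -> nn.Tensor:
        """Batched forward: int ids (B, L) -> Tensor (B, L, d_out)."""
        ids = np.asarray(ids)
        # scaled by sqrt(d) as in the image tower
        x = nn.embedding_lookup(self.table, ids) * np.sqrt(self.config.d_out)
        return x + nn.constant(
            positional_encoding(ids.shape[-1], self.config.d_out)
        )

    def embed(self, text: str) -> EmbeddingSequence:
        ids = np.asarray([tokenize(text, self.vocab)])
        out = self.forward(ids)
        return EmbeddingSequence(
            out.data[0],
            modality="text",
            source_id=hashlib.sha1(text.strip().encode()).hexdigest()[:12],
        )


def embed_text(text: str, tower: TextTower) -> EmbeddingSequence:
    return tower.embed(text)


# ----------------------------------------------- precomputed embedding files
def save_precomputed_embeddings(path, table: dict) -> None:
    """Write source_id -> (L x D) tables as TSV: source_id, position, D floats."""
    with open(path, "w") as fh:
        for sid, seq in table.items():
            arr = np.asarray(seq, dtype=np.float64)
            for pos, row in enumerate(arr):
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{sid}\t{pos}\t{vals}\n")


def load_precomputed_embeddings(path) -> dict:
    """Load a TSV embedding table; validates a uniform dimensionality."""
    rows: dict = {}
    dim = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 columns")
            sid, pos, vals = parts[0], int(parts[1]), parts[2:]
            if dim is None:
                dim = len(vals)
            elif len(vals) != dim:
                raise FormatError(
                    f"line {lineno}: dimension {len(vals)} != {dim}"
                )
            rows.setdefault(sid, []).append((pos, [float(v) for v in vals]))
    table = {}
    for sid, items in rows.items():
        items.sort(key=lambda x: x[0])
        table[sid] = np.array([v for _, v in items], dtype=np.float64)
    return table
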