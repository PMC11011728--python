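"""Training objectives and the learning-rate schedule.

The central objective is the multimodal contrastive (InfoNCE-style) loss over
a batch of matched image/text projections:

    L = -(1/n) sum_i log[ exp(sim(x_i, y_i)/tau) / sum_j exp(sim(x_i, y_j)/tau) ]

where sim is cosine similarity and tau a temperature.  An optional symmetric
variant averages the image->text and text->image directions.  The
noise-contrastive-estimation loss, softmax cross-entropy and the linear
warmup + cosine-annealed learning-rate schedule are also provided here.

All losses accept either plain numpy arrays (returning a float) or autodiff
Tensors (returning a Tensor usable for backpropagation).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .exceptions import DegenerateInputError

PROB_EPS = 1e-12  # floor inside log() for probability-space cross-entropy


def cosine_similarity(a, b) -> float:
    """cos(a, b) = <a,b> / (|a||b|); zero vectors are rejected, not mapped to 0."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("cosine similarity undefined for zero vector")
    return float(a @ b / (na * nb))


def _normalize_rows(x: nn.Tensor) -> nn.Tensor:
    norms = (x * x).sum(axis=1, keepdims=True).sqrt()
    return x / norms


def cosine_similarity_matrix(x: nn.Tensor, y: nn.Tensor) -> nn.Tensor:
    """All-pairs cosine similarities: S[i, j] = cos(x_i, y_j)."""
    return _normalize_rows(x) @ _normalize_rows(y).transpose((1, 0))


def multimodal_contrastive_loss(x, y, tau: float = 0.1, symmetric: bool = False):
    """InfoNCE loss over matched projection rows of x (image) and y (text).

    Matched pairs share a row index; every other row in the batch is an
    in-batch negative.  Computed via a numerically stable log-softmax.
    Returns a float for array inputs, a Tensor for Tensor inputs.
    """
    as_tensor = isinstance(x, nn.Tensor) or isinstance(y, nn.Tensor)
    xt = x if isinstance(x, nn.Tensor) else nn.constant(np.atleast_2d(x))
    yt = y if isinstance(y, nn.Tensor) else nn.constant(np.atleast_2d(y))
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    n = xt.shape[0]
    if (np.linalg.norm(xt.data, axis=1) == 0).any() or (
        np.linalg.norm(yt.data, axis=1) == 0
    ).any():
        raise DegenerateInputError("zero-norm projection row")

    logits = cosine_similarity_matrix(xt, yt) * (1.0 / tau)
    diag = (np.arange(n), np.arange(n))
    loss = -(nn.log_softmax(logits, axis=1)[diag]).mean()
    if symmetric:
        loss_t2i = -(nn.log_softmax(logits.transpose((1, 0)), axis=1)[diag]).mean()
        loss = (loss + loss_t2i) * 0.5
    return loss if as_tensor else loss.item()


def nce_loss(p_true, p_noise, k: int = 1) -> float:
    """Noise-contrastive estimation loss.

    L = -(1/n) sum_i log[ p(x_i) / (p(x_i) + k * p_n(x_i)) ], with k noise
    samples per true sample.
    """
    p = np.asarray(p_true, dtype=np.float64).ravel()
    pn = np.asarray(p_noise, dtype=np.float64).ravel()
    if p.shape != pn.shape:
        raise ValueError("p_true and p_noise must share length")
    if k < 1:
        raise ValueError("k must be >= 1")
    if (p < 0).any() or (pn < 0).any():
        raise ValueError("densities must be non-negative")
    denom = p + k * pn
    if (denom == 0).any():
        raise DegenerateInputError("p(x) + k*p_n(x) must be > 0 elementwise")
    return float(-np.mean(np.log(p / denom)))


def cross_entropy(probabilities, label: int) -> float:
    """-log p[label] for a probability simplex vector (epsilon-floored)."""
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    if not 0 <= label < p.size:
        raise IndexError(f"label {label} out of range for {p.size} classes")
    return float(-np.log(max(p[label], PROB_EPS)))


def cross_entropy_logits(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Mean softmax cross-entropy from logits (the training-path form)."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    logp = nn.log_softmax(logits, axis=1)
    return -(logp[(np.arange(n), labels)]).mean()


def lr_schedule(
    step: int,
    base_lr: float,
    warmup_epochs: int,
    total_epochs: int,
    steps_per_epoch: int,
    floor_lr: float = 0.0,
) -> float:
    """Linear warmup to `base_lr` then cosine-annealed decay to `floor_lr`.

    The ramp is 0 -> base_lr over the warmup steps (exactly base_lr at the
    warmup boundary); afterwards
    lr = floor + (base - floor) * 0.5 * (1 + cos(pi * progress)).
    """
    if warmup_epochs >= total_epochs:
        raise ValueError("warmup_epochs must be < total_epochs")
    warmup_steps = warmup_epochs * steps_per_epoch
    total_steps = total_epochs * steps_per_epoch
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * step / warmup_steps
    denom = max(total_steps - warmup_steps, 1)
    progress = (step - warmup_steps) / denom
    return floor_lr + (base_lr - floor_lr) * 0.5 * (1.0 + np.cos(np.pi * progress))
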