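"""Multimodal projection head, joint-space fusion and the MLP phase classifier.

Each encoder's pooled output passes through its own projection head — a
feed-forward network (two fully connected layers with a ReLU between them)
followed by a final linear layer that maps into the joint space.  The joint
representation is the concatenation of the two projected vectors (image part
first) and feeds a small MLP whose softmax output gives the seven phase
probabilities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import nn
from .exceptions import ConfigurationError

N_PHASES = 7


@dataclasses.dataclass
class JointRepresentation:
    vector: np.ndarray
    provenance: tuple = (None, None)  # (image source_id, text source_id)

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if not np.isfinite(self.vector).all():
            raise ValueError("joint representation contains non-finite entries")


@dataclasses.dataclass
class PhasePrediction:
    probabilities: np.ndarray
    predicted_phase: int

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if abs(self.probabilities.sum() - 1.0) > 1e-8:
            raise ValueError("probabilities must sum to 1")


class ProjectionHead(nn.Module):
    """FFN (linear -> ReLU -> linear) then a final linear map to d_joint."""

    def __init__(self, d_in: int, d_joint: int, rng, d_hidden: int | None = None):
        d_hidden = d_in if d_hidden is None else d_hidden
        self.fc1 = nn.Linear(d_in, d_hidden, rng)
        self.fc2 = nn.Linear(d_hidden, d_in, rng)
        self.out = nn.Linear(d_in, d_joint, rng)

    def __call__(self, h) -> nn.Tensor:
        h = h if isinstance(h, nn.Tensor) else nn.constant(np.atleast_2d(h))
        if h.shape[-1] != self.fc1.w.shape[0]:
            raise ConfigurationError(
                f"input dim {h.shape[-1]} != head dim {self.fc1.w.shape[0]}"
            )
        return self.out(self.fc2(self.fc1(h).relu()))

    def project(self, h: np.ndarray) -> np.ndarray:
        """Single-vector convenience wrapper."""
        return self(np.atleast_2d(h)).data[0]


def projection_head(h: np.ndarray, head: ProjectionHead) -> np.ndarray:
    return head.project(h)


def combine_joint(h_img, h_txt, provenance=(None, None)) -> JointRepresentation:
    """Concatenate projected modality vectors, image part first."""
    return JointRepresentation(
        vector=np.concatenate(
            [np.asarray(h_img).ravel(), np.asarray(h_txt).ravel()]
        ),
        provenance=tuple(provenance),
    )


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class MLPClassifier(nn.Module):
    """One-hidden-layer MLP with a softmax over the seven phases."""

    def __init__(self, d_in: int, rng, d_hidden: int = 128,
                 n_classes: int = N_PHASES):
        self.fc1 = nn.Linear(d_in, d_hidden, rng)
        self.fc2 = nn.Linear(d_hidden, n_classes, rng)
        self.n_classes = n_classes

    def logits(self, j) -> nn.Tensor:
        x = j if isinstance(j, nn.Tensor) else nn.constant(np.atleast_2d(j))
        if x.shape[-1] != self.fc1.w.shape[0]:
            raise ConfigurationError(
                f"input dim {x.shape[-1]} != classifier dim {self.fc1.w.shape[0]}"
            )
        return self.fc2(self.fc1(x).relu())

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(np.atleast_2d(x)).data)

    def predict(self, j) -> PhasePrediction:
        vec = j.vector if isinstance(j, JointRepresentation) else np.asarray(j)
        probs = self.predict_proba(vec)[0]
        # np.argmax breaks ties toward the lowest class index
        return PhasePrediction(
            probabilities=probs, predicted_phase=int(np.argmax(probs))
        )


def mlp_forward(j: JointRepresentation, mlp: MLPClassifier) -> PhasePrediction:
    return mlp.predict(j)


def predictions_to_csv(records, path) -> None:
    """Write rows (video_id, frame_index, PhasePrediction) as the documented CSV."""
    rows = []
    for vid, fi, pred in records:
        row = {"video_id": vid, "frame_index": fi,
               "predicted_phase": pred.predicted_phase}
        for c, p in enumerate(pred.probabilities):
            row[f"p{c}"] = p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
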