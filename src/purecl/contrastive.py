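"""Projection head and the supervised contrastive (SupCon) loss.

For a batch of N source images augmented into 2N views with projections
z_i on the unit hypersphere and view labels y_i, the loss is

    L = sum_i  -1/|P(i)| * sum_{p in P(i)} log[ exp(z_i.z_p / tau)
                                / sum_{a in A(i)} exp(z_i.z_a / tau) ]

where A(i) is every view except i and P(i) = {p in A(i) : y_p = y_i}.
``supcon_loss`` is the vectorized, log-sum-exp-stabilized implementation
used for training; ``supcon_loss_oracle`` is a literal triple-loop
transcription kept for cross-checking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .augment import PositivePair
from .encoder import FeaturePurificationEncoder, FilterMode
from .exceptions import DataError, DegenerateInputError
from .nn import Tensor

__all__ = [
    "ProjectionHead",
    "MultiviewBatch",
    "project",
    "supcon_loss",
    "supcon_loss_oracle",
    "build_multiview_batch",
]

PROJECTION_DIM = 256
HIDDEN_DIM = 2048


class ProjectionHead(nn.Module):
    """Two-layer perceptron (2048 hidden, 256 out) with unit-norm output.

    Used only during contrastive pretraining and discarded afterwards.
    """

    def __init__(self, rng: np.random.Generator | int = 0, in_dim: int = 2048,
                 hidden_dim: int = HIDDEN_DIM, out_dim: int = PROJECTION_DIM):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.fc1 = nn.Linear(in_dim, hidden_dim, rng)
        self.fc2 = nn.Linear(hidden_dim, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        if not np.isfinite(x.data).all():
            raise DegenerateInputError("projection input contains non-finite values")
        y = self.fc2(nn.relu(self.fc1(x)))
        norms = np.linalg.norm(y.data, axis=-1)
        if np.any(norms < 1e-8):
            raise DegenerateInputError(
                "cannot normalize a zero vector onto the unit hypersphere"
            )
        return nn.l2_normalize(y, axis=-1)


def project(embedding, params: ProjectionHead) -> Tensor:
    """Project one embedding (or a batch) onto the 256-d unit hypersphere."""
    arr = embedding if isinstance(embedding, Tensor) else Tensor(np.atleast_2d(embedding))
    return params(arr)


@dataclass
class MultiviewBatch:
    """2N projected views with their labels and the softmax temperature."""

    projections: Tensor  # (2N, d), rows unit-norm
    labels: np.ndarray   # (2N,) int
    temperature: float = 0.07

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.projections.shape[0] != len(self.labels):
            raise DataError("projections and labels disagree in length")
        if self.temperature <= 0:
            raise DataError("temperature must be positive")


def _positive_mask(labels: np.ndarray) -> np.ndarray:
    eq = labels[:, None] == labels[None, :]
    np.fill_diagonal(eq, False)
    return eq


def supcon_loss(batch: MultiviewBatch, reduction: str = "mean_over_anchors") -> Tensor:
    """Vectorized SupCon loss; differentiable through ``batch.projections``.

    reduction="sum" is the literal sum over anchors; "mean_over_anchors"
    divides by the number of views for batch-size-independent logging.
    """
    if reduction not in ("sum", "mean_over_anchors"):
        raise ValueError(f"unknown reduction {reduction!r}")
    z = batch.projections
    labels = batch.labels
    m = z.shape[0]
    pos = _positive_mask(labels)
    pos_counts = pos.sum(axis=1)
    if np.any(pos_counts == 0):
        i = int(np.argmin(pos_counts))
        raise DataError(f"anchor {i} (label {labels[i]}) has no positive in the batch")
    sim = (z @ z.T) * (1.0 / batch.temperature)
    # exclude self-similarity from the denominator via a -inf-like offset
    self_block = Tensor(np.where(np.eye(m, dtype=bool), -1e9, 0.0).astype(z.dtype))
    lse = nn.logsumexp(sim + self_block, axis=1)          # (m,)
    mean_pos = (sim * Tensor(pos.astype(z.dtype))).sum(axis=1) * Tensor(
        (1.0 / pos_counts).astype(z.dtype))
    per_anchor = lse - mean_pos
    total = per_anchor.sum()
    if reduction == "mean_over_anchors":
        return total * (1.0 / m)
    return total


def supcon_loss_oracle(batch: MultiviewBatch, reduction: str = "mean_over_anchors") -> float:
    """Literal triple-loop transcription of the loss — no vectorization, no
    stabilization.  Test oracle only."""
    z = np.asarray(batch.projections.data if isinstance(batch.projections, Tensor)
                   else batch.projections, dtype=np.float64)
    labels = batch.labels
    tau = batch.temperature
    m = len(labels)
    total = 0.0
    for i in range(m):
        positives = [p for p in range(m) if p != i and labels[p] == labels[i]]
        if not positives:
            raise DataError(f"anchor {i} (label {labels[i]}) has no positive in the batch")
        denom = 0.0
        for a in range(m):
            if a != i:
                denom += math.exp(float(z[i] @ z[a]) / tau)
        inner = 0.0
        for p in positives:
            inner += math.log(math.exp(float(z[i] @ z[p]) / tau) / denom)
        total += -inner / len(positives)
    if reduction == "mean_over_anchors":
        return total / m
    return total


def build_multiview_batch(pairs: list[PositivePair],
                          encoder: FeaturePurificationEncoder,
                          projector: ProjectionHead,
                          temperature: float = 0.07,
                          mode: FilterMode = FilterMode.SUBTRACT) -> MultiviewBatch:
    """Encode and project 2N views (interleaved a0, b0, a1, b1, ...)."""
    if len(pairs) < 2:
        raise DataError("need at least two positive pairs to form a multiview batch")
    labels = np.repeat([p.label for p in pairs], 2)
    if len(set(p.label for p in pairs)) < 2:
        warnings.warn("multiview batch contains a single class: no negatives to contrast",
                      stacklevel=2)
    views = np.stack([v for p in pairs for v in (p.view_a, p.view_b)]).astype(np.float32)
    embeddings = encoder(Tensor(views), mode)
    projections = projector(embeddings)
    return MultiviewBatch(projections=projections, labels=labels, temperature=temperature)
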