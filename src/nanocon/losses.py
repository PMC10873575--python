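"""Contrastive pairing and the training losses.

The contrastive objective operates on pairs built by deterministically
shuffling a batch and splitting it into two equal halves; pair *i* couples
element *i* of each half, with indicator ``y = 1`` when the two share a
class.  The loss is

    L = 1/(2N) * sum[ (1 - y) * D(x_i, x_j)^2
                      + y * max(margin - D(x_i, x_j), 0)^2 ]

with D the cosine similarity and margin 2.  Implemented exactly in this
form: same-class pairs are pushed toward high similarity through the margin
hinge, different-class pairs toward zero similarity through the quadratic
term.  Note that with cosine similarity bounded by 1 and margin 2 the
same-class hinge never saturates — the pull toward alignment is always
active; this is a documented property of the formulation, not a defect.

The classification loss is the mean binary cross-entropy, and the combined
objective is ``alpha * L_contrastive + (1 - alpha) * L_CE`` with
``alpha = 0.8`` by default.  All losses accept either plain arrays (for
evaluation) or autodiff Tensors (inside the training loop), through the same
code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._autograd import Tensor

__all__ = ["LossConfig", "ContrastivePairBatch", "make_pairs",
           "cosine_similarity", "contrastive_loss", "cross_entropy_loss",
           "combined_loss"]

EPSILON = 1e-7  # probability clamp for the cross-entropy


@dataclass(frozen=True)
class LossConfig:
    """Contrastive margin and combined-loss weighting."""

    margin: float = 2.0
    alpha: float = 0.8

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class ContrastivePairBatch:
    """Indices (or representations) of paired instances with y indicators."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    y: np.ndarray  # 1 where the paired instances share a class

    def __post_init__(self) -> None:
        if not (len(self.idx_a) == len(self.idx_b) == len(self.y)):
            raise ValueError("pair components must have equal length")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary")

    def __len__(self) -> int:
        return len(self.y)


def make_pairs(labels: Sequence[int], seed: int) -> ContrastivePairBatch:
    """Shuffle a batch and pair its two halves.

    The batch is permuted deterministically by ``seed`` and split into two
    equal halves (one leftover element of an odd batch is dropped); pair *i*
    is (half1[i], half2[i]) and ``y_i = 1`` iff their labels agree.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2:
        raise ValueError(f"need at least 2 instances to pair, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    half = n // 2
    idx_a, idx_b = order[:half], order[half:2 * half]
    y = (labels[idx_a] == labels[idx_b]).astype(np.int64)
    return ContrastivePairBatch(idx_a=idx_a, idx_b=idx_b, y=y)


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def cosine_similarity(x_i, x_j):
    """Rowwise cosine similarity ``x_i . x_j / (|x_i| |x_j|)``.

    Accepts single vectors or (n, d) batches; Tensor inputs stay
    differentiable.  Zero vectors are rejected (the similarity is undefined).
    """
    x_i, x_j = _lift(x_i), _lift(x_j)
    norm_i = (x_i ** 2).sum(axis=-1).sqrt()
    norm_j = (x_j ** 2).sum(axis=-1).sqrt()
    if np.any(norm_i.data == 0) or np.any(norm_j.data == 0):
        raise ValueError("cosine similarity undefined for zero vectors")
    sim = (x_i * x_j).sum(axis=-1) / (norm_i * norm_j)
    return sim


def contrastive_loss(reprs_a, reprs_b, y, margin: float = 2.0):
    """Margin contrastive loss over paired representations.

    ``1/(2N) * sum[(1-y) D^2 + y max(margin - D, 0)^2]`` with D the rowwise
    cosine similarity between ``reprs_a`` and ``reprs_b``.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n == 0:
        raise ValueError("empty pair batch")
    d = cosine_similarity(reprs_a, reprs_b)
    hinge = ((-d) + margin).maximum(0.0)
    per_pair = (1.0 - y) * d ** 2 + y * hinge ** 2
    return per_pair.sum() * (1.0 / (2.0 * n))


def cross_entropy_loss(p, labels):
    """Mean binary cross-entropy over predicted P(label = 1).

    Probabilities are clamped to [eps, 1 - eps] before the logs so that
    saturated predictions stay finite.
    """
    p = _lift(p)
    if not np.all(np.isfinite(p.data)):
        raise ValueError("non-finite probabilities")
    labels = np.asarray(labels, dtype=np.float64)
    if len(labels) == 0:
        raise ValueError("empty batch")
    p = p.clip(EPSILON, 1.0 - EPSILON)
    per_sample = -(labels * p.log() + (1.0 - labels) * (1.0 - p).log())
    return per_sample.mean()


def combined_loss(loss_contrastive, loss_ce, alpha: float = 0.8):
    """Weighted training objective: alpha * contrastive + (1 - alpha) * CE."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * loss_contrastive + (1.0 - alpha) * loss_ce
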