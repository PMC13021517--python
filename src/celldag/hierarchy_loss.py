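"""Flat and hierarchical cross-entropy over an ontology's reachability matrix.

Standard cross-entropy treats the ``C`` cell types as independent classes:
for a predicted distribution ``p`` and true class ``t`` the per-sample loss
is ``-w_t * log(p_t + eps)``.  Hierarchical cross-entropy (HCE) instead
scores the *adjusted* probability

    s_i = p_i + sum of p_j over all descendants j of i,

computed for every class at once as the matrix-vector product ``s = R p``
with ``R`` the reachability matrix, and takes ``-w_t * log(s_t + eps)``.
Probability mass placed on any subtype of the annotated label therefore
counts toward it: a cell annotated "T cell" is explained equally well by a
confident "CD4-positive, alpha-beta T cell" prediction.  On an edge-free
ontology ``R`` is the identity and the two losses coincide exactly.

Class weights follow the inverse-frequency convention
``w_i = N / (C * n_i)``; classes with no training samples get weight zero
(they cannot be learned) and are flagged.

All functions accept a single probability vector or a batch (rows = cells).
``loss_and_grad`` additionally returns the analytic gradient with respect
to the pre-softmax scores, which is what the training loop consumes; its
closed form is

    dL/dz_k = -(w_t / (s_t + eps)) * p_k * (R[t, k] - s_t),

of which flat CE is the ``R = I`` special case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ClassWeights",
    "LossConfig",
    "softmax",
    "compute_class_weights",
    "adjust_scores",
    "ce_loss",
    "hce_loss",
    "loss_and_grad",
]

DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class LossConfig:
    """Loss hyperparameters.

    ``epsilon`` stabilises the logarithm as ``log(s + eps)`` — added after
    descendant aggregation, and reused identically in the flat CE for
    parity.  ``weighted`` toggles inverse-frequency class weights.
    """

    epsilon: float = DEFAULT_EPSILON
    weighted: bool = True

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights ``w_i = N / (C * n_i)``."""

    w: np.ndarray
    N: int
    counts: np.ndarray

    @property
    def absent(self) -> np.ndarray:
        """Boolean mask of classes with no training samples (weight 0)."""
        return self.counts == 0

    def __getitem__(self, i) -> float:
        return self.w[i]


def compute_class_weights(labels: Sequence[int], n_classes: int) -> ClassWeights:
    """Inverse-frequency weights from training label indices.

    Classes absent from ``labels`` receive weight 0 and are flagged via
    :attr:`ClassWeights.absent` — ``N / (C * 0)`` is undefined and an
    absent class cannot be learned.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("cannot compute class weights from an empty label list")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"label indices must lie in [0, {n_classes}), "
            f"got range [{labels.min()}, {labels.max()}]"
        )
    counts = np.bincount(labels, minlength=n_classes).astype(np.int64)
    n_total = int(labels.size)
    w = np.zeros(n_classes, dtype=np.float64)
    present = counts > 0
    w[present] = n_total / (n_classes * counts[present])
    if not present.all():
        logger.warning(
            "%d of %d classes have no training samples; their weight is 0",
            int((~present).sum()),
            n_classes,
        )
    return ClassWeights(w=w, N=n_total, counts=counts)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax (max-shifted for stability)."""
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _check_probabilities(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    if (p < -atol).any():
        raise ValueError("probabilities must be nonnegative")
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValueError(
            f"probability rows must sum to 1 within {atol}; got sums {sums}"
        )
    return p


def adjust_scores(p: np.ndarray, reachability: np.ndarray) -> np.ndarray:
    """Hierarchy-adjusted scores ``s = R p``.

    ``s_i`` aggregates the probability of class ``i`` and of every
    descendant, each counted exactly once regardless of how many is_a
    paths connect them.  Accepts a vector or a batch (one row per cell)
    and preserves the input's dimensionality.
    """
    p = np.asarray(p, dtype=np.float64)
    r = np.asarray(reachability)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    if p2.shape[1] != r.shape[0] or r.shape[0] != r.shape[1]:
        raise ValueError(
            f"dimension mismatch: p has {p2.shape[1]} classes, "
            f"R is {r.shape[0]}x{r.shape[1]}"
        )
    s = p2 @ r.T.astype(np.float64)
    return s[0] if single else s


def _weight_of(w, labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Resolve a ClassWeights / array / scalar / None into per-sample weights."""
    if w is None:
        return np.ones(labels.shape, dtype=np.float64)
    if isinstance(w, ClassWeights):
        w = w.w
    w = np.asarray(w, dtype=np.float64)
    if w.ndim == 0:
        return np.full(labels.shape, float(w))
    if w.shape != (n_classes,):
        raise ValueError(f"expected {n_classes} class weights, got shape {w.shape}")
    return w[labels]


def ce_loss(
    p: np.ndarray,
    true_label,
    weights=None,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Weighted flat cross-entropy ``-w_t * log(p_t + eps)``.

    A single probability vector yields the per-sample loss.  Over a batch
    (2-D input) the reduction is the weighted mean: sum of weighted
    per-sample losses divided by the sum of the participating weights.
    A sample whose true class has weight 0 contributes nothing; if every
    sample in the batch is such, the loss is 0 and a warning is logged.
    """
    return hce_loss(p, true_label, None, weights=weights, epsilon=epsilon)


def hce_loss(
    p: np.ndarray,
    true_label,
    reachability: np.ndarray | None,
    weights=None,
    epsilon: float = DEFAULT_EPSILON,
    config: LossConfig | None = None,
) -> float:
    """Weighted hierarchical cross-entropy ``-w_t * log(s_t + eps)``.

    ``reachability=None`` means the identity (edge-free ontology), which
    makes this exactly :func:`ce_loss`.  Batch reduction as in
    :func:`ce_loss`.
    """
    if config is not None:
        epsilon = config.epsilon
        if not config.weighted:
            weights = None
    single = np.asarray(p).ndim == 1
    p2 = _check_probabilities(p)
    labels = np.atleast_1d(np.asarray(true_label, dtype=np.int64))
    if labels.shape[0] != p2.shape[0]:
        raise ValueError("one true label per probability row is required")
    if reachability is None:
        s_t = p2[np.arange(len(labels)), labels]
    else:
        s = adjust_scores(p2, reachability)
        s_t = s[np.arange(len(labels)), labels]
    w = _weight_of(weights, labels, p2.shape[1])
    if single:
        return float(-w[0] * np.log(s_t[0] + epsilon))
    w_sum = w.sum()
    if w_sum == 0:
        logger.warning(
            "all samples in the batch have weight 0 (true classes absent from "
            "training); loss is 0"
        )
        return 0.0
    return float((-w * np.log(s_t + epsilon)).sum() / w_sum)


def loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    weights,
    reachability: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[float, np.ndarray]:
    """Batched loss and its analytic gradient w.r.t. the pre-softmax scores.

    Returns ``(loss, grad)`` where ``grad`` has the shape of ``logits``.
    With ``reachability=None`` this is weighted flat CE; otherwise HCE.
    The two share one gradient formula because flat CE is the
    ``R = identity`` special case.
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    n, c = logits.shape
    p = softmax(logits)
    if reachability is None:
        r_rows = np.zeros((n, c), dtype=np.float64)
        r_rows[np.arange(n), labels] = 1.0
    else:
        r_rows = np.asarray(reachability, dtype=np.float64)[labels]
    s_t = (p * r_rows).sum(axis=1)
    w = _weight_of(weights, labels, c)
    w_sum = w.sum()
    if w_sum == 0:
        return 0.0, np.zeros_like(logits)
    loss = float((-w * np.log(s_t + epsilon)).sum() / w_sum)
    coef = -(w / (s_t + epsilon)) / w_sum
    grad = coef[:, None] * p * (r_rows - s_t[:, None])
    return loss, grad
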