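"""Training objectives for every learning paradigm, as pure functions.

All losses accept numpy arrays or autodiff :class:`~harspectrum.nn.Tensor`
inputs and return a Tensor (so the same code path serves unit tests on hand
values and gradient-based training).  The printed definitions are sums over
samples/pairs; trainers pass ``reduction="mean"`` for batch-size-independent
steps, and the sum form is what the unit tests check.

Conventions:

* reconstruction (autoencoder) loss: mean over the batch of the squared
  Euclidean reconstruction error;
* contrastive loss on a pair with binary similarity label y and margin delta:
  ``y * D**2 / 2 + (1 - y) * max(0, delta - D)**2 / 2`` where D is the
  (non-squared) Euclidean embedding distance — dissimilar pairs farther than
  the margin contribute nothing (hard-negative gating);
* temporal / feature consistency: squared error between a sample's
  reconstruction and the *inputs* of its temporal / feature-space neighbors,
  averaged over the neighborhood;
* the self-supervised joint loss mixes reconstruction with the two
  consistency terms on the (1-alpha-beta, alpha, beta) simplex, and the
  weakly self-supervised joint loss additionally mixes in the activity
  contrastive term with weight gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, astensor

__all__ = [
    "LossWeights", "ContrastiveBreakdown",
    "reconstruction_loss", "similarity_distance", "contrastive_loss",
    "cross_entropy_loss", "cross_entropy_from_logits", "multitask_loss",
    "temporal_consistency_loss", "feature_consistency_loss",
    "selfsup_loss", "weak_selfsup_loss",
]

_SQRT_EPS = 1e-24  # inside the sqrt of the pair distance; keeps d(x, x) differentiable


@dataclass(frozen=True)
class LossWeights:
    """Mixing weights for the joint objectives and the contrastive margin."""

    alpha: float = 0.3
    beta: float = 0.3
    gamma: float = 0.0
    margin_delta: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("weights must be >= 0")
        if self.alpha + self.beta + self.gamma > 1 + 1e-12:
            raise ValueError("alpha + beta + gamma must be <= 1")
        if self.margin_delta <= 0:
            raise ValueError("margin_delta must be > 0")


@dataclass
class ContrastiveBreakdown:
    """Per-pair diagnostics of the contrastive loss."""

    D: np.ndarray              # Euclidean distances
    Ls: np.ndarray             # similar-pair terms D^2/2
    Ld: np.ndarray             # dissimilar-pair terms max(0, delta-D)^2/2
    per_pair_loss: np.ndarray  # y*Ls + (1-y)*Ld


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("pair labels must be binary (0 or 1)")
    return y


def _reduce(per_item: Tensor, reduction: str) -> Tensor:
    if reduction == "sum":
        return per_item.sum()
    if reduction == "mean":
        return per_item.mean()
    raise ValueError(f"unknown reduction {reduction!r}")


def reconstruction_loss(x, x_recon, reduction: str = "mean") -> Tensor:
    """Mean (or sum) over the batch of squared reconstruction error."""
    x, x_recon = astensor(x), astensor(x_recon)
    if x.shape != x_recon.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_recon.shape}")
    n = x.shape[0] if x.ndim > 1 else 1
    flat_x = x.reshape(n, -1)
    flat_r = x_recon.reshape(n, -1)
    per_sample = ((flat_x - flat_r) ** 2).sum(axis=1)
    return _reduce(per_sample, reduction)


def similarity_distance(fa, fb) -> Tensor:
    """Euclidean distance between embeddings (last axis), non-squared."""
    fa, fb = astensor(fa), astensor(fb)
    return (((fa - fb) ** 2).sum(axis=-1) + _SQRT_EPS).sqrt()


def contrastive_loss(fa, fb, y, delta: float = 1.0,
                     reduction: str = "sum") -> tuple[Tensor, ContrastiveBreakdown]:
    """Pairwise margin contrastive loss over embedding batches.

    Similar pairs (y=1) are penalized by half their squared distance; the
    squared distance is used directly so identical positives stay
    differentiable.  Dissimilar pairs (y=0) are penalized only inside the
    margin delta.
    """
    if delta <= 0:
        raise ValueError("margin delta must be > 0")
    fa, fb = astensor(fa), astensor(fb)
    if fa.ndim == 1:
        fa, fb = fa.reshape(1, -1), fb.reshape(1, -1)
    y = _check_labels(np.atleast_1d(y))
    sq = ((fa - fb) ** 2).sum(axis=1)          # D^2, no sqrt
    d = (sq + _SQRT_EPS).sqrt()
    ls = sq * 0.5
    hinge = (float(delta) - d).relu()
    ld = hinge * hinge * 0.5
    per_pair = y * ls + (1.0 - y) * ld
    total = _reduce(per_pair, reduction)
    breakdown = ContrastiveBreakdown(D=d.value.copy(), Ls=ls.value.copy(),
                                     Ld=ld.value.copy(),
                                     per_pair_loss=per_pair.value.copy())
    return total, breakdown


def cross_entropy_loss(y_true, y_prob, reduction: str = "mean") -> Tensor:
    """Cross-entropy between one-hot targets and predicted probabilities."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=np.float64))
    y_prob = astensor(y_prob)
    p = y_prob if y_prob.ndim > 1 else y_prob.reshape(1, -1)
    if not np.allclose(p.value.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("predicted probabilities must sum to 1 per sample")
    # only the true-class terms survive; mask before log to avoid log(0)
    # contributions from classes with y=0
    logp = (p + (1.0 - y_true)).log()  # adds 1 where y=0 -> log(..) masked out below
    per_sample = -(y_true * logp).sum(axis=1)
    return _reduce(per_sample, reduction)


def cross_entropy_from_logits(logits: Tensor, y_onehot: np.ndarray,
                              reduction: str = "mean") -> Tensor:
    """Numerically stable softmax + cross-entropy for classifier training."""
    z = astensor(logits)
    m = Tensor(z.value.max(axis=1, keepdims=True))  # constant shift
    shifted = z - m
    logsumexp = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - logsumexp
    per_sample = -(np.asarray(y_onehot, dtype=np.float64) * logp).sum(axis=1)
    return _reduce(per_sample, reduction)


def multitask_loss(phi_act, phi_pers, alpha: float = 0.5, beta: float = 0.5) -> Tensor:
    """Weighted sum of the activity- and person-head contrastive losses."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    return alpha * astensor(phi_act) + beta * astensor(phi_pers)


def _consistency(x_recon, neighbors) -> Tensor:
    x_recon = astensor(x_recon)
    neigh = np.atleast_2d(np.asarray(neighbors, dtype=np.float64))
    per_neighbor = ((Tensor(neigh) - x_recon.reshape(1, -1)) ** 2).sum(axis=1)
    return per_neighbor.mean()


def temporal_consistency_loss(x_recon, neighbors) -> Tensor:
    """Mean squared error between one sample's reconstruction and the inputs
    of its temporal neighborhood P (center included)."""
    return _consistency(x_recon, neighbors)


def feature_consistency_loss(x_recon, neighbors) -> Tensor:
    """Mean squared error between one sample's reconstruction and the inputs
    of its feature-space neighborhood Q (self excluded)."""
    return _consistency(x_recon, neighbors)


def _neighbor_moments(neighbor_sets: list[np.ndarray]):
    """Per-sample neighbor mean and mean squared norm.

    Because sum_p ||x_p - r||^2 / |P| expands to
    ||r||^2 - 2 <r, mean_p x_p> + mean_p ||x_p||^2, the consistency terms of a
    whole batch only need these two moments — identical in value to the
    literal per-neighbor sum.
    """
    means = np.stack([np.atleast_2d(s).mean(axis=0) for s in neighbor_sets])
    msn = np.array([(np.atleast_2d(s) ** 2).sum(axis=1).mean() for s in neighbor_sets])
    return means, msn


def _consistency_batch(recon: Tensor, neighbor_sets) -> Tensor:
    """Batch of consistency terms; accepts either a list of per-sample
    neighbor-input arrays or a precomputed ``(means, msn)`` moment pair."""
    if isinstance(neighbor_sets, tuple):
        means, msn = neighbor_sets
    else:
        means, msn = _neighbor_moments(neighbor_sets)
    sq = (recon ** 2).sum(axis=1)
    cross = (recon * means).sum(axis=1)
    return sq - 2.0 * cross + msn


def neighbor_moments_table(features: np.ndarray,
                           index_table: dict[int, np.ndarray]):
    """Precompute (means, msn) for every sample of a dataset, so trainers can
    slice per batch instead of rebuilding neighbor lists each step."""
    n = features.shape[0]
    means = np.empty_like(features)
    msn = np.empty(n)
    sq = (features ** 2).sum(axis=1)
    for i in range(n):
        nb = index_table[i]
        means[i] = features[nb].mean(axis=0)
        msn[i] = sq[nb].mean()
    return means, msn


def selfsup_loss(x, x_recon, tc_neighbors: list[np.ndarray],
                 fc_neighbors: list[np.ndarray], weights: LossWeights,
                 reduction: str = "sum") -> tuple[Tensor, dict[str, float]]:
    """Joint self-supervised objective: per sample,
    ``(1-a-b)*Phi_ae + a*Phi_tc + b*Phi_fc``, summed (or averaged) over the
    batch.  Returns the total and the per-term totals (same reduction), which
    re-sum exactly to the total.
    """
    a, b = weights.alpha, weights.beta
    if a + b > 1 + 1e-12:
        raise ValueError("alpha + beta must be <= 1")
    x = astensor(x)
    recon = astensor(x_recon)
    ae = ((x - recon) ** 2).sum(axis=1)
    tc = _consistency_batch(recon, tc_neighbors)
    fc = _consistency_batch(recon, fc_neighbors)
    per_sample = (1.0 - a - b) * ae + a * tc + b * fc
    total = _reduce(per_sample, reduction)
    parts = {
        "ae": float(_reduce((1.0 - a - b) * ae, reduction).value),
        "tc": float(_reduce(a * tc, reduction).value),
        "fc": float(_reduce(b * fc, reduction).value),
    }
    return total, parts


def weak_selfsup_loss(xa, xb, recon_a, recon_b, emb_a, emb_b, y_act,
                      tc_neighbors_a, fc_neighbors_a,
                      tc_neighbors_b, fc_neighbors_b,
                      weights: LossWeights,
                      reduction: str = "sum") -> tuple[Tensor, dict[str, float]]:
    """Second-stage joint objective of the weakly self-supervised scheme:
    reconstruction + consistency regularizers on both branches, plus the
    activity contrastive term with weight gamma.
    """
    a, b, g = weights.alpha, weights.beta, weights.gamma
    if a + b + g > 1 + 1e-12:
        raise ValueError("alpha + beta + gamma must be <= 1")
    xa, xb = astensor(xa), astensor(xb)
    ra, rb = astensor(recon_a), astensor(recon_b)
    ae = ((xa - ra) ** 2).sum(axis=1) + ((xb - rb) ** 2).sum(axis=1)
    tc = (_consistency_batch(ra, tc_neighbors_a)
          + _consistency_batch(rb, tc_neighbors_b))
    fc = (_consistency_batch(ra, fc_neighbors_a)
          + _consistency_batch(rb, fc_neighbors_b))
    simi, _ = contrastive_loss(emb_a, emb_b, y_act, delta=weights.margin_delta,
                               reduction="sum")
    if reduction == "mean":
        n = xa.shape[0]
        simi = simi / n
    per_pair_reg = (1.0 - a - b - g) * ae + a * tc + b * fc
    reg_total = _reduce(per_pair_reg, reduction)
    total = reg_total + g * simi
    parts = {
        "ae": float(_reduce((1.0 - a - b - g) * ae, reduction).value),
        "tc": float(_reduce(a * tc, reduction).value),
        "fc": float(_reduce(b * fc, reduction).value),
        "simi_act": float((g * simi).value),
    }
    return total, parts
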