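"""Training objectives: reconstruction cross-entropy, triplet loss,
similarity loss and their combination.

All functions accept autodiff Tensors (for training) or plain arrays (wrapped
as constants) and return a scalar Tensor; use ``.item()`` for the float value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor
from .tokenizer import PAD_ID

EPS = 1e-12


@dataclass(frozen=True)
class TripletParams:
    m: float = 1.0

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("margin m must be >= 0")


@dataclass(frozen=True)
class SimilarityLossParams:
    a: float = 20.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("scaling factor a must be > 0")


def _l2(x: Tensor) -> Tensor:
    # clamp keeps the gradient finite when two latents coincide exactly;
    # above 1e-12 distance the value is bit-identical to the plain norm
    return (x * x).sum(axis=-1).maximum(1e-24).sqrt()


def reconstruction_loss(probs, targets, reduction: str = "sum") -> Tensor:
    """Cross entropy -sum_i sum_c t_{i,c} log p_{i,c} over non-PAD positions.

    probs: [..., T, V] predicted distributions; targets: [..., T] integer
    classes. PAD target positions are excluded. `reduction` "sum" (the
    per-token sum) or "mean" (per-token average).
    """
    probs = astensor(probs)
    targets = np.asarray(targets)
    keep = (targets != PAD_ID)
    if not keep.any():
        raise ValueError("no non-PAD target positions")
    # gather p at the true class, clamp to avoid log(0)
    onehot = np.zeros(probs.shape)
    grid = list(np.indices(targets.shape))
    onehot[tuple(grid) + (targets,)] = 1.0
    onehot *= keep[..., None]
    picked = (probs * onehot).sum(axis=-1) + (1.0 - keep)  # PAD rows -> log(1)=0
    nll = -(picked.maximum(EPS).log()).sum()
    if reduction == "mean":
        return nll * (1.0 / keep.sum())
    if reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return nll


def logits_reconstruction_loss(logits: Tensor, targets,
                               reduction: str = "mean") -> Tensor:
    """Numerically stable cross entropy straight from logits (training path)."""
    targets = np.asarray(targets)
    keep = (targets != PAD_ID)
    logp = logits.log_softmax(axis=-1)
    grid = tuple(np.indices(targets.shape))
    picked = logp[grid + (targets,)]  # gather true-class log-probs
    nll = -(picked * keep.astype(logp.data.dtype)).sum()
    if reduction == "mean":
        return nll * (1.0 / max(keep.sum(), 1))
    return nll


def triplet_loss(fA, fP, fN, params: TripletParams = TripletParams()) -> Tensor:
    """max(||f(A)-f(P)|| - ||f(A)-f(N)|| + m, 0)."""
    fA, fP, fN = astensor(fA), astensor(fP), astensor(fN)
    hinge = _l2(fA - fP) - _l2(fA - fN) + params.m
    return hinge.maximum(0.0)


def similarity_loss(fA, fX, sim_AX: float,
                    params: SimilarityLossParams = SimilarityLossParams()) -> Tensor:
    """| a*(1 - sim(A,X)) - ||f(A)-f(X)|| |."""
    sim = float(sim_AX)
    if not 0.0 <= sim <= 1.0:
        raise ValueError(f"similarity {sim} outside [0, 1]")
    fA, fX = astensor(fA), astensor(fX)
    target = params.a * (1.0 - sim)
    return (target - _l2(fA - fX)).abs()


def batch_similarity_loss(latents, anchor_indices, sims,
                          params: SimilarityLossParams = SimilarityLossParams()
                          ) -> Tensor:
    """Mean similarity loss over all (anchor, X != anchor) pairs in a batch.

    latents: [B, d] Tensor; anchor_indices: iterable of batch positions;
    sims: [B, B] ground-truth similarity slice aligned with the batch.
    """
    latents = astensor(latents)
    sims = np.asarray(sims, dtype=np.float64)
    B = latents.shape[0]
    if B < 2:
        raise ValueError("batch of size 1 has no pairs")
    anchors = list(anchor_indices)
    if not anchors:
        raise ValueError("no anchors given")
    if any(a < 0 or a >= B for a in anchors):
        raise ValueError("anchor index outside batch")
    if np.any(sims < 0) or np.any(sims > 1):
        raise ValueError("similarities outside [0, 1]")

    total = None
    count = 0
    for a in anchors:
        others = [j for j in range(B) if j != a]
        fa = latents[a].reshape(1, latents.shape[1])
        fx = latents[others]
        dist = _l2(fa - fx)  # [B-1]
        target = params.a * (1.0 - sims[a, others])
        term = (Tensor(target) - dist).abs().sum()
        total = term if total is None else total + term
        count += len(others)
    return total * (1.0 / count)


def batch_triplet_loss(latents, anchor_indices, sims,
                       params: TripletParams = TripletParams(),
                       pos_threshold: float = 0.5) -> Tensor:
    """Batch-all triplet loss for the baseline.

    Positives: batch members with sim >= pos_threshold to the anchor;
    negatives: sim < pos_threshold. Mean hinge over all (P, N) pairs across
    anchors that have both classes; returns 0 if no anchor does.
    """
    latents = astensor(latents)
    sims = np.asarray(sims, dtype=np.float64)
    B = latents.shape[0]
    total = None
    count = 0
    for a in anchor_indices:
        others = np.array([j for j in range(B) if j != a])
        pos = others[sims[a, others] >= pos_threshold]
        neg = others[sims[a, others] < pos_threshold]
        if len(pos) == 0 or len(neg) == 0:
            continue
        fa = latents[a].reshape(1, latents.shape[1])
        dp = _l2(fa - latents[pos])  # [P]
        dn = _l2(fa - latents[neg])  # [N]
        hinge = (dp.reshape(len(pos), 1) - dn.reshape(1, len(neg))
                 + params.m).maximum(0.0)
        total = hinge.sum() if total is None else total + hinge.sum()
        count += len(pos) * len(neg)
    if total is None:
        return Tensor(0.0)
    return total * (1.0 / count)


def combined_loss(reconstruction, shape_term, weight: float = 1.0) -> Tensor:
    """reconstruction + weight * shape_term (weight 1 = the plain sum)."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    return astensor(reconstruction) + weight * astensor(shape_term)
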