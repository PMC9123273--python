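"""Segmentation and classification losses.

The segmentation stage trains under a Focal Tversky loss: the Tversky index
generalizes Dice by weighting false negatives and false positives
asymmetrically,

    TI = TP / (TP + alpha*FN + beta*FP),

and the loss focuses training on hard volumes by raising its complement to
an exponent, FTL = (1 - TI)**gamma. The classification stage trains under
the focal loss FL(p_t) = -alpha * (1 - p_t)**gamma * log(p_t), which
down-weights easy examples relative to plain cross-entropy.

These are the numpy reference implementations; the trainable graph versions
live in :mod:`strokekit.nn`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TverskyParams",
    "FocalParams",
    "tversky_index",
    "focal_tversky_loss",
    "focal_loss",
    "EPS",
]

EPS = 1e-6


@dataclass(frozen=True)
class TverskyParams:
    """Weights of the Tversky index and focusing exponent of its loss.

    ``alpha`` weights false negatives, ``beta`` false positives; with
    alpha = beta = 0.5 the index reduces to the Dice coefficient. ``gamma``
    is the focusing exponent of the focal Tversky loss. The defaults follow
    the values commonly used for lesion segmentation (alpha 0.7, beta 0.3,
    gamma 4/3).
    """

    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 4.0 / 3.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class FocalParams:
    """Balancing weight ``alpha`` in (0, 1] and focusing exponent ``gamma``."""

    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


def _soft_counts(pred_probs, truth):
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    tp = float((p * t).sum())
    fn = float(((1.0 - p) * t).sum())
    fp = float((p * (1.0 - t)).sum())
    return tp, fn, fp


def tversky_index(pred_probs, truth, params: TverskyParams = TverskyParams()) -> float:
    """Soft Tversky index TP/(TP + alpha*FN + beta*FP) with smoothing EPS."""
    tp, fn, fp = _soft_counts(pred_probs, truth)
    return (tp + EPS) / (tp + params.alpha * fn + params.beta * fp + EPS)


def focal_tversky_loss(pred_probs, truth,
                       params: TverskyParams = TverskyParams()) -> float:
    """(1 - TI)**gamma; zero for a perfect prediction."""
    ti = tversky_index(pred_probs, truth, params)
    return float((1.0 - ti) ** params.gamma)


def focal_loss(prob_true_class, params: FocalParams = FocalParams()) -> float:
    """Focal loss -alpha*(1-p_t)**gamma*log(p_t), averaged over a batch.

    ``prob_true_class`` is the predicted probability of the *true* class of
    each sample. Probabilities of exactly zero are clamped to a small
    epsilon with a warning because the log diverges there.
    """
    p = np.atleast_1d(np.asarray(prob_true_class, dtype=np.float64))
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p_t must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p_t of 0 clamped to epsilon (log divergence)",
                      RuntimeWarning, stacklevel=2)
        p = np.clip(p, 1e-12, None)
    losses = -params.alpha * (1.0 - p) ** params.gamma * np.log(p)
    return float(losses.mean())
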