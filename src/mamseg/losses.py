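"""Class-weighted losses for the three-class segmentation problem.

Two losses address the pectoral-muscle class imbalance (the pectoral class
is rare and small, especially in CC views):

* weighted cross-entropy:  L = -sum_c alpha_c log p_t,c
* weighted focal loss:     L = -sum_c alpha_c (1 - p_t,c)^gamma log p_t,c

with, per pixel of ground truth y,

    p_t,c = p_c        if y = c
            1 - p_c    otherwise,

so every class contributes a term at every pixel - for non-true classes the
model is rewarded for assigning them *low* probability.  Setting gamma = 0
makes the focal loss coincide with the weighted cross-entropy.  Losses are
averaged over pixels so their magnitude is independent of crop size.

The class-weight convention is alpha = [1, 1, alpha_pectoral].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LossConfig", "weighted_cross_entropy", "focal_loss", "evaluate_loss",
           "loss_and_logit_grad"]

_EPS = 1e-12  # clamp for log and its denominator


@dataclass(frozen=True)
class LossConfig:
    """Loss selection: type, per-class weights and focusing exponent."""

    loss_type: str = "cross_entropy"
    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gamma: float = 2.0

    def __post_init__(self):
        if self.loss_type not in ("cross_entropy", "focal"):
            raise ValueError("loss_type must be 'cross_entropy' or 'focal'")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("alpha must be positive elementwise")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    @classmethod
    def with_pectoral_weight(cls, loss_type: str, alpha_pectoral: float,
                             gamma: float = 2.0) -> "LossConfig":
        return cls(loss_type=loss_type, alpha=(1.0, 1.0, float(alpha_pectoral)),
                   gamma=gamma)


def _as_batches(probs: np.ndarray, truth: np.ndarray):
    probs = np.asarray(probs, dtype=np.float64)
    truth_arr = getattr(truth, "labels", truth)
    truth_arr = np.asarray(truth_arr)
    if probs.ndim == 3:
        probs = probs[None]
    if truth_arr.ndim == 2:
        truth_arr = truth_arr[None]
    if probs.shape[0] != truth_arr.shape[0] or probs.shape[2:] != truth_arr.shape[1:]:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {truth_arr.shape}")
    return probs, truth_arr


def _pt(probs: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """p_t,c per pixel and class: p_c for the true class, 1-p_c otherwise."""
    n_classes = probs.shape[1]
    onehot = (truth[:, None] == np.arange(n_classes)[None, :, None, None])
    return np.where(onehot, probs, 1.0 - probs)


def weighted_cross_entropy(probs, truth, alpha=(1.0, 1.0, 1.0)) -> float:
    """Pixel-mean weighted cross-entropy over all classes.

    ``probs`` is (classes, H, W) or (N, classes, H, W); ``truth`` holds
    integer class labels of matching spatial shape.
    """
    probs, truth = _as_batches(probs, truth)
    alpha = np.asarray(alpha, dtype=np.float64)
    pt = np.clip(_pt(probs, truth), _EPS, 1.0)
    per_pixel = -(alpha[None, :, None, None] * np.log(pt)).sum(axis=1)
    return float(per_pixel.mean())


def focal_loss(probs, truth, alpha=(1.0, 1.0, 1.0), gamma: float = 2.0) -> float:
    """Pixel-mean weighted focal loss; gamma=0 reduces to cross-entropy."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    probs, truth = _as_batches(probs, truth)
    alpha = np.asarray(alpha, dtype=np.float64)
    pt = np.clip(_pt(probs, truth), _EPS, 1.0)
    per_pixel = -(alpha[None, :, None, None] * (1.0 - pt) ** gamma * np.log(pt)).sum(axis=1)
    return float(per_pixel.mean())


def evaluate_loss(probs, truth, config: LossConfig) -> float:
    """Dispatch on :class:`LossConfig`."""
    if config.loss_type == "cross_entropy":
        return weighted_cross_entropy(probs, truth, config.alpha)
    return focal_loss(probs, truth, config.alpha, config.gamma)


def loss_and_logit_grad(logits: np.ndarray, truth: np.ndarray,
                        config: LossConfig) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits.

    Used by the training loop: the loss is defined on softmax probabilities,
    and the gradient is pulled back through the softmax Jacobian
    d x_i = p_i (g_i - sum_j g_j p_j) with g = dL/dp.
    """
    from .unet import softmax_channels

    truth_arr = getattr(truth, "labels", truth)
    truth_arr = np.asarray(truth_arr)
    if truth_arr.ndim == 2:
        truth_arr = truth_arr[None]
    probs = softmax_channels(logits.astype(np.float64))
    alpha = np.asarray(config.alpha, dtype=np.float64)[None, :, None, None]
    n_classes = probs.shape[1]
    onehot = (truth_arr[:, None] == np.arange(n_classes)[None, :, None, None])
    pt = np.where(onehot, probs, 1.0 - probs)
    ptc = np.clip(pt, _EPS, 1.0)
    gamma = config.gamma if config.loss_type == "focal" else 0.0
    if gamma == 0.0:
        loss_pix = -(alpha * np.log(ptc)).sum(axis=1)
        dldpt = -alpha / ptc
    else:
        omt = 1.0 - pt
        loss_pix = -(alpha * omt ** gamma * np.log(ptc)).sum(axis=1)
        dldpt = alpha * (gamma * np.clip(omt, 0.0, None) ** max(gamma - 1.0, 0.0)
                         * np.log(ptc) - omt ** gamma / ptc)
    sign = np.where(onehot, 1.0, -1.0)
    g = dldpt * sign                          # dL/dp_c
    inner = (g * probs).sum(axis=1, keepdims=True)
    npix = probs.shape[0] * probs.shape[2] * probs.shape[3]
    dlogits = (probs * (g - inner) / npix).astype(np.float32)
    return float(loss_pix.mean()), dlogits
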