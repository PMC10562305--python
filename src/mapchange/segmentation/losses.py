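"""Focal loss for dense multi-class segmentation.

Focal loss down-weights easy pixels: with true-class probability ``p_t``
the per-pixel loss is ``-alpha_t * (1 - p_t)**gamma * log(p_t)``. At
``gamma = 0`` it reduces exactly to (weighted) cross-entropy. Map sheets
are dominated by background pixels, which is the class-imbalance regime
the loss was designed for.
"""

from __future__ import annotations

import numpy as np

__all__ = ["focal_loss", "focal_loss_with_logits"]

_EPS = 1e-12


def _resolve_alpha(alpha, n_classes: int) -> np.ndarray:
    if alpha is None:
        return np.ones(n_classes)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape != (n_classes,):
        raise ValueError(f"alpha must have one weight per class ({n_classes})")
    return alpha


def focal_loss(
    class_probabilities: np.ndarray,
    target: np.ndarray,
    gamma: float = 2.0,
    alpha=None,
) -> float:
    """Mean focal loss over pixels.

    ``class_probabilities`` carries the class axis last (any leading pixel
    axes); each pixel's distribution must sum to 1. ``target`` holds integer
    class labels with the same leading shape.
    """
    probs = np.asarray(class_probabilities, dtype=np.float64)
    target = np.asarray(target)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if probs.shape[:-1] != target.shape:
        raise ValueError("probability and target shapes do not align")
    sums = probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("class probabilities must be normalized per pixel")
    n_classes = probs.shape[-1]
    alpha = _resolve_alpha(alpha, n_classes)
    flat = probs.reshape(-1, n_classes)
    t = target.reshape(-1)
    p_t = np.clip(flat[np.arange(t.size), t], _EPS, 1.0)
    loss = -alpha[t] * (1.0 - p_t) ** gamma * np.log(p_t)
    return float(loss.mean())


def focal_loss_with_logits(
    logits: np.ndarray, target: np.ndarray, gamma: float = 2.0, alpha=None
):
    """Loss and gradient w.r.t. logits, for training.

    ``logits`` is (N, C, H, W); ``target`` is (N, H, W) int. Returns
    ``(loss, dlogits)`` where the gradient corresponds to the mean-over-
    pixels reduction.

    The gradient follows from d(p_j)/d(z_k) = p_j (delta_jk - p_k):

        dL/dz_k = s * (p_k - delta_tk),
        s = alpha_t * ((1-p_t)**gamma - gamma * p_t * (1-p_t)**(gamma-1) * log p_t)

    which collapses to the softmax cross-entropy gradient at gamma = 0.
    """
    n, c, h, w = logits.shape
    alpha = _resolve_alpha(alpha, c)
    z = logits.astype(np.float64) - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)  # (N, C, H, W)

    flat_p = p.transpose(0, 2, 3, 1).reshape(-1, c)
    t = np.asarray(target).reshape(-1)
    idx = np.arange(t.size)
    p_t = np.clip(flat_p[idx, t], _EPS, 1.0)
    log_pt = np.log(p_t)
    one_m = 1.0 - p_t
    a_t = alpha[t]
    loss = float((-a_t * one_m**gamma * log_pt).mean())

    if gamma == 0:
        s = a_t
    else:
        # (1-p_t)**(gamma-1) explodes only when p_t -> 1, where log p_t -> 0
        s = a_t * (one_m**gamma - gamma * p_t * np.where(
            one_m > _EPS, one_m ** (gamma - 1.0), 0.0
        ) * log_pt)

    grad = flat_p * s[:, None]
    grad[idx, t] -= s
    grad /= t.size
    dlogits = grad.reshape(n, h, w, c).transpose(0, 3, 1, 2)
    return loss, dlogits.astype(np.float32)
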