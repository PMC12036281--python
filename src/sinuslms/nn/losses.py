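"""Combined soft-Dice + cross-entropy segmentation loss.

The loss is ``ce_weight * CE + dice_weight * (1 - mean soft Dice over
foreground classes)``, the usual pairing for class-imbalanced medical
segmentation: cross-entropy drives per-pixel calibration while the Dice
term directly optimizes overlap of the (small) foreground regions.
Gradients with respect to the logits are computed analytically through
the softmax.
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "dice_ce_loss"]


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_ce_loss(
    logits: np.ndarray,
    targets: np.ndarray,
    dice_weight: float = 1.0,
    ce_weight: float = 1.0,
    smooth: float = 1e-5,
) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. ``logits``.

    Parameters
    ----------
    logits : (B, K, H, W) class scores
    targets : (B, H, W) integer labels in [0, K)

    Soft Dice is computed per foreground class over the whole batch
    (class 0 is background) with additive smoothing, then averaged.
    """
    B, K, H, W = logits.shape
    p = softmax(logits, axis=1)
    onehot = np.zeros_like(p)
    bidx, hidx, widx = np.meshgrid(
        np.arange(B), np.arange(H), np.arange(W), indexing="ij"
    )
    onehot[bidx, targets, hidx, widx] = 1.0

    n_pix = B * H * W
    p_true = p[bidx, targets, hidx, widx]
    ce = float(-np.log(np.maximum(p_true, 1e-12)).mean())
    dce = (p - onehot) / n_pix

    axes = (0, 2, 3)
    inter = (p * onehot).sum(axis=axes)
    num = 2.0 * inter + smooth
    den = p.sum(axis=axes) + onehot.sum(axis=axes) + smooth
    d_per_class = num / den
    n_fg = K - 1
    dice_loss = float(1.0 - d_per_class[1:].mean())

    # dL/dp_c = -(2 t_c den_c - num_c) / den_c^2 / n_fg for foreground c
    g = -(2.0 * onehot * den[None, :, None, None] - num[None, :, None, None]) / (
        den[None, :, None, None] ** 2
    ) / n_fg
    g[:, 0] = 0.0
    ddice = p * (g - (g * p).sum(axis=1, keepdims=True))

    loss = ce_weight * ce + dice_weight * dice_loss
    dlogits = (ce_weight * dce + dice_weight * ddice).astype(logits.dtype)
    return loss, dlogits
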