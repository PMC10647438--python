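"""Segmentation losses on soft (probability) predictions.

All losses accept the foreground-probability tensor and a binary reference
mask of the same shape, and reduce to a scalar over the whole batch.
Tversky with alpha = beta = 0.5 is algebraically identical to soft Dice.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .nn import Tensor, as_tensor

DICE_EPS = 1e-5


def _check(probabilities, mask) -> tuple[Tensor, Tensor]:
    p = as_tensor(probabilities)
    g = as_tensor(np.asarray(mask.data if isinstance(mask, Tensor) else mask))
    if p.shape != g.shape:
        raise ValidationError(f"prediction {p.shape} vs mask {g.shape}", field="shape")
    if np.any(p.data < -1e-6) or np.any(p.data > 1 + 1e-6):
        raise ValidationError("probabilities must lie in [0, 1]", field="probabilities")
    return p, g


def soft_dice_loss(probabilities, mask, epsilon: float = DICE_EPS) -> Tensor:
    """1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)."""
    p, g = _check(probabilities, mask)
    inter = (p * g).sum()
    return 1.0 - (2.0 * inter + epsilon) / (p.sum() + g.sum() + epsilon)


def tversky_loss(probabilities, mask, alpha: float = 0.3, beta: float = 0.7,
                 epsilon: float = DICE_EPS) -> Tensor:
    """1 - (TP + eps) / (TP + alpha*FP + beta*FN + eps) with soft counts.

    alpha weights false positives, beta false negatives; (0.5, 0.5)
    recovers soft Dice. Defaults follow the loss's original formulation.
    """
    if alpha < 0 or beta < 0 or alpha + beta <= 0:
        raise ValidationError("alpha, beta must be >= 0 with alpha + beta > 0",
                              field="alpha/beta")
    p, g = _check(probabilities, mask)
    tp = (p * g).sum()
    fp = (p * (1.0 - g)).sum()
    fn = ((1.0 - p) * g).sum()
    return 1.0 - (tp + epsilon) / (tp + alpha * fp + beta * fn + epsilon)


def dice_ce_loss(probabilities, mask, epsilon: float = DICE_EPS,
                 clip: float = 1e-7) -> Tensor:
    """Soft Dice plus voxel-mean binary cross-entropy, equally weighted."""
    p, g = _check(probabilities, mask)
    pc = p.clip(clip, 1.0 - clip)
    ce = -(g * pc.log() + (1.0 - g) * (1.0 - pc).log()).mean()
    return soft_dice_loss(p, g, epsilon=epsilon) + ce


LOSSES = {"dice": soft_dice_loss, "dice_ce": dice_ce_loss, "tversky": tversky_loss}
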