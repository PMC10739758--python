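"""The composite training objective L_t = beta1 * L_s1 + beta2 * L_s2.

L_s1 is a per-sample soft dice loss computed on temperature-softened
class probabilities, with the sums running jointly over classes and
pixels of the sample; it drives pixel-level overlap and is robust to the
heavy background/foreground imbalance of greenhouse scenes. L_s2 is the
temperature-softened cross-entropy, averaged over samples and pixels,
which stabilizes convergence when predicted probabilities and targets
are small. The temperature tau divides the logits before the softmax
(tau = 1 recovers the standard softmax; the tuned default is 1.5), and
the weights satisfy beta1 + beta2 = 1 with defaults 0.9 / 0.1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor

_LOG_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class LossConfig:
    beta1: float = 0.9
    beta2: float = 0.1
    tau: float = 1.5
    c_se: int = 4

    def __post_init__(self):
        if abs(self.beta1 + self.beta2 - 1.0) > 1e-9:
            raise ValueError(
                f"beta1 + beta2 must equal 1, got {self.beta1} + {self.beta2}")
        if not (0.0 <= self.beta1 <= 1.0):
            raise ValueError("beta1 must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError(f"temperature must be positive, got {self.tau}")
        if self.c_se < 2:
            raise ValueError("need at least two classes")


def one_hot(mask: np.ndarray, c_se: int = 4) -> np.ndarray:
    """(N, H, W) integer mask -> (N, c_se, H, W) one-hot float array."""
    if mask.min() < 0 or mask.max() >= c_se:
        raise ValueError(f"labels outside [0, {c_se})")
    return np.moveaxis(np.eye(c_se)[mask], -1, 1)


def temperature_softmax(logits: Tensor, tau: float) -> Tensor:
    """softmax(logits / tau) over the class axis (axis 1).

    Larger tau softens the distribution toward uniform while preserving
    the ordering of class probabilities; tau = 1 is the standard softmax.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    return T.softmax(logits * (1.0 / tau), axis=1)


def soft_dice_loss(target: np.ndarray, probs: Tensor) -> Tensor:
    """Per-sample soft dice loss, averaged over the batch; value in [0, 1].

    ``target`` is one-hot (N, c, H, W); ``probs`` a congruent probability
    map. The dice sums run jointly over classes and pixels per sample:
    1 - 2*sum(T*p) / sum(T^2 + p^2).
    """
    if target.shape != probs.shape:
        raise ValueError(f"target {target.shape} vs probs {probs.shape}")
    axes = (1, 2, 3)
    num = 2.0 * (Tensor(target) * probs).sum(axis=axes)
    den = Tensor((target ** 2).sum(axis=axes)) + (probs ** 2).sum(axis=axes) + _LOG_EPS
    return (1.0 - num / den).mean()


def temperature_cross_entropy(target: np.ndarray, logits: Tensor,
                              tau: float) -> Tensor:
    """Cross-entropy against temperature-softened probabilities.

    Averaged over samples and pixels (each pixel is a classification
    sample); log probabilities are floored at 1e-12, so the loss is
    finite even for a confidently wrong prediction.
    """
    if target.shape != logits.shape:
        raise ValueError(f"target {target.shape} vs logits {logits.shape}")
    probs = temperature_softmax(logits, tau)
    logp = T.log(probs + _LOG_EPS)
    per_pixel = -(Tensor(target) * logp).sum(axis=1)      # (N, H, W)
    return per_pixel.mean()


def total_loss(target: np.ndarray, logits: Tensor, config: LossConfig):
    """Returns (L_t, L_s1, L_s2) as tensors.

    A component with zero weight is not evaluated at all (its slot holds a
    constant zero), so degenerate weightings skip the unused term.
    """
    if config.beta1 > 0:
        probs = temperature_softmax(logits, config.tau)
        l_s1 = soft_dice_loss(target, probs)
    else:
        l_s1 = Tensor(0.0)
    if config.beta2 > 0:
        l_s2 = temperature_cross_entropy(target, logits, config.tau)
    else:
        l_s2 = Tensor(0.0)
    l_t = config.beta1 * l_s1 + config.beta2 * l_s2
    return l_t, l_s1, l_s2
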