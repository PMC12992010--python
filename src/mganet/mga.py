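"""Mask-Guided Attention: lesion-probability masks steer feature maps.

The segmentation branch emits a per-pixel lesion probability map.  This
module resizes that map bilinearly to the spatial size of an
intermediate feature map F(C, H, W), min-max normalises it per image,

    mask_norm = (mask_resized - min) / (max - min + eps),

and enhances F along two parallel paths fed the same normalised mask:

    spatial   F_s = F (*) mask_norm                       (broadcast over C)
    channel   F_c = F (*) MLP(GAP(F (*) mask_norm))       (per-channel gate)
    fused     F'  = F_s + F_c + F                         (residual sum)

The channel MLP is a squeeze-excitation-shaped two-layer perceptron
(C -> C/r -> C, ReLU inside, sigmoid out).  No part of the mask path is
detached, so classification gradients flow back into the segmentation
branch — the property that makes joint training collaborative.

Ablation variants: ``spatial_only`` (F_s + F), ``channel_only``
(F_c + F), ``serial`` (channel gate computed on the spatial branch's
output, plus residual) and ``none`` (identity).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor, as_tensor

__all__ = [
    "VARIANTS",
    "ChannelMLP",
    "MaskGuidedAttention",
    "resize_mask",
    "normalize_mask",
    "spatial_attention",
    "channel_attention",
    "mga_forward",
    "mga_variant_forward",
]

VARIANTS = ("parallel", "spatial_only", "channel_only", "serial", "none")
DEFAULT_EPS = 1e-6
DEFAULT_REDUCTION = 16
MIN_HIDDEN = 4


def resize_mask(mask: Tensor, height: int, width: int) -> Tensor:
    """Bilinear resize of a (B, 1, H_m, W_m) mask to (B, 1, height, width)."""
    return ag.bilinear_resize(as_tensor(mask), height, width)


def normalize_mask(mask_resized: Tensor, eps: float = DEFAULT_EPS) -> Tensor:
    """Per-image min-max normalisation into [0, 1); ``eps`` guards the
    constant-mask case, which maps to all zeros."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    m = as_tensor(mask_resized)
    axes = tuple(range(1, m.ndim))  # every axis but the batch axis
    lo = ag.amin(m, axis=axes, keepdims=True)
    hi = ag.amax(m, axis=axes, keepdims=True)
    return (m - lo) / (hi - lo + eps)


def spatial_attention(F: Tensor, mask_norm: Tensor) -> Tensor:
    """F_s = F (*) mask_norm, the single-channel mask broadcast across C."""
    F, mask_norm = as_tensor(F), as_tensor(mask_norm)
    if F.shape[-2:] != mask_norm.shape[-2:]:
        raise ValueError(
            f"spatial shapes differ: {F.shape[-2:]} vs {mask_norm.shape[-2:]}")
    return F * mask_norm


def channel_attention(F: Tensor, mask_norm: Tensor, mlp) -> Tensor:
    """F_c = F (*) mlp(GAP(F (*) mask_norm)).

    ``mlp`` maps a (B, C) pooled descriptor to (B, C) gating
    coefficients; any callable with that contract is accepted, which is
    how the ablation stubs enter in tests.
    """
    masked = spatial_attention(F, mask_norm)
    pooled = masked.mean(axis=(-2, -1))  # GAP -> (B, C) or (C,)
    coeff = mlp(pooled)
    gate_shape = coeff.shape + (1, 1)
    return as_tensor(F) * coeff.reshape(gate_shape)


class ChannelMLP(nn.Module):
    """Squeeze-excitation-shaped gate: C -> max(C // r, 4) -> C, sigmoid out."""

    def __init__(self, channels: int, reduction: int = DEFAULT_REDUCTION, *,
                 rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, MIN_HIDDEN)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(x))))


def mga_forward(F: Tensor, mask: Tensor, mlp, eps: float = DEFAULT_EPS) -> Tensor:
    """Parallel fusion F' = F_s + F_c + F; both branches share one mask_norm."""
    return mga_variant_forward(F, mask, mlp, "parallel", eps)


def mga_variant_forward(F: Tensor, mask: Tensor, mlp, variant: str,
                        eps: float = DEFAULT_EPS) -> Tensor:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    F = as_tensor(F)
    if variant == "none":
        return F
    mask_norm = normalize_mask(resize_mask(mask, F.shape[-2], F.shape[-1]), eps)
    if variant == "spatial_only":
        return spatial_attention(F, mask_norm) + F
    if variant == "channel_only":
        return channel_attention(F, mask_norm, mlp) + F
    if variant == "serial":
        F_s = spatial_attention(F, mask_norm)
        return channel_attention(F_s, mask_norm, mlp) + F
    F_s = spatial_attention(F, mask_norm)
    F_c = channel_attention(F, mask_norm, mlp)
    return F_s + F_c + F


class MaskGuidedAttention(nn.Module):
    """The attention block inserted into the classification backbone."""

    def __init__(self, channels: int, reduction: int = DEFAULT_REDUCTION,
                 variant: str = "parallel", eps: float = DEFAULT_EPS, *,
                 rng: np.random.Generator):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.eps = eps
        self.mlp = ChannelMLP(channels, reduction, rng=rng)

    def forward(self, F: Tensor, mask: Tensor) -> Tensor:
        return mga_variant_forward(F, mask, self.mlp, self.variant, self.eps)
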