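"""The dual-branch model: residual classifier + UNet-style segmenter.

The classification branch is a 34-layer residual network (stem plus
stages of 3/4/6/3 basic blocks) ending in global average pooling and a
two-way affine head.  Mask-guided attention blocks are inserted at the
configured scales: L0 is the stem output (after the first conv/pool),
L1–L4 the four residual stages.  ``placement='per_layer'`` enhances
once after each selected stage; ``'per_block'`` after every residual
block of the selected stages.

The segmentation branch is an encoder–decoder: an 18-layer residual
encoder (2/2/2/2 basic blocks) with skip connections into a bilinear
upsampling decoder, closed by a single-channel sigmoid head at input
resolution.  Its probability map conditions every attention block in
the classifier; the mask path is never detached, so both branches are
optimised jointly by the classification loss.

All channel widths scale with ``width_multiplier`` (floored at 4),
which is how the CPU-scale test models are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor, as_tensor
from .config import INSERTION_POINTS, ModelConfig
from .mga import MaskGuidedAttention

__all__ = [
    "DualOutput",
    "SegmentationBranch",
    "ClassificationBackbone",
    "DualBranchModel",
    "build_segmentation_branch",
    "build_classification_backbone",
    "build_model",
    "forward_dual",
]

_BASE_WIDTHS = (64, 64, 128, 256, 512)  # stem, L1..L4
_CLS_BLOCKS = (3, 4, 6, 3)  # 34-layer configuration
_SEG_BLOCKS = (2, 2, 2, 2)  # 18-layer configuration


def _scale(width: int, multiplier: float) -> int:
    return max(4, int(round(width * multiplier)))


@dataclass
class DualOutput:
    class_logits: Tensor  # (B, 2)
    seg_prob: Tensor | None  # (B, 1, H, W) in [0, 1]
    enhanced_features: dict = field(default_factory=dict)  # point -> Tensor


class BasicBlock(nn.Module):
    """Two 3x3 convolutions with identity (or projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, *, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                       bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def forward(self, x):
        identity = x
        out = ag.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x))
        return ag.relu(out + identity)


def _make_stage(in_ch: int, out_ch: int, n_blocks: int, stride: int, *, rng):
    blocks = [BasicBlock(in_ch, out_ch, stride, rng=rng)]
    blocks += [BasicBlock(out_ch, out_ch, 1, rng=rng) for _ in range(n_blocks - 1)]
    return nn.ModuleList(blocks)


class _DecoderStage(nn.Module):
    """Upsample x2, concatenate the matching encoder skip, fuse with conv."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, *, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch + skip_ch, out_ch, 3, padding=1,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x, skip):
        x = ag.bilinear_resize(x, skip.shape[-2], skip.shape[-1])
        x = ag.concat([x, skip], axis=1)
        return ag.relu(self.bn(self.conv(x)))


class SegmentationBranch(nn.Module):
    """UNet-shaped network with an 18-layer residual encoder."""

    def __init__(self, config: ModelConfig, *, rng: np.random.Generator):
        super().__init__()
        if config.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        wm = config.width_multiplier
        w = [_scale(c, wm) for c in _BASE_WIDTHS]
        self.stem_conv = nn.Conv2d(1, w[0], 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(w[0])
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stage1 = _make_stage(w[0], w[1], _SEG_BLOCKS[0], 1, rng=rng)
        self.stage2 = _make_stage(w[1], w[2], _SEG_BLOCKS[1], 2, rng=rng)
        self.stage3 = _make_stage(w[2], w[3], _SEG_BLOCKS[2], 2, rng=rng)
        self.stage4 = _make_stage(w[3], w[4], _SEG_BLOCKS[3], 2, rng=rng)
        self.dec3 = _DecoderStage(w[4], w[3], w[3], rng=rng)
        self.dec2 = _DecoderStage(w[3], w[2], w[2], rng=rng)
        self.dec1 = _DecoderStage(w[2], w[1], w[1], rng=rng)
        self.dec0 = _DecoderStage(w[1], w[0], w[0] // 2, rng=rng)
        self.head = nn.Conv2d(w[0] // 2, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        size = x.shape[-1]
        x0 = ag.relu(self.stem_bn(self.stem_conv(x)))  # H/2
        h = self.pool(x0)
        for blk in self.stage1:
            h = blk(h)
        x1 = h  # H/4
        for blk in self.stage2:
            h = blk(h)
        x2 = h  # H/8
        for blk in self.stage3:
            h = blk(h)
        x3 = h  # H/16
        for blk in self.stage4:
            h = blk(h)  # H/32
        d = self.dec3(h, x3)
        d = self.dec2(d, x2)
        d = self.dec1(d, x1)
        d = self.dec0(d, x0)
        d = ag.bilinear_resize(d, size, size)
        return ag.sigmoid(self.head(d))


class ClassificationBackbone(nn.Module):
    """34-layer residual classifier with mask-guided attention insertions."""

    def __init__(self, config: ModelConfig, *, rng: np.random.Generator):
        super().__init__()
        self.config = config
        wm = config.width_multiplier
        w = [_scale(c, wm) for c in _BASE_WIDTHS]
        self.stem_conv = nn.Conv2d(1, w[0], 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(w[0])
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stage1 = _make_stage(w[0], w[1], _CLS_BLOCKS[0], 1, rng=rng)
        self.stage2 = _make_stage(w[1], w[2], _CLS_BLOCKS[1], 2, rng=rng)
        self.stage3 = _make_stage(w[2], w[3], _CLS_BLOCKS[2], 2, rng=rng)
        self.stage4 = _make_stage(w[3], w[4], _CLS_BLOCKS[3], 2, rng=rng)
        self.fc = nn.Linear(w[4], config.num_classes, rng=rng)

        self._stage_widths = {"L0": w[0], "L1": w[1], "L2": w[2],
                              "L3": w[3], "L4": w[4]}
        self._stage_nblocks = {"L0": 1, "L1": _CLS_BLOCKS[0], "L2": _CLS_BLOCKS[1],
                               "L3": _CLS_BLOCKS[2], "L4": _CLS_BLOCKS[3]}
        self.attention = nn.ModuleList()
        self._att_index: dict[tuple[str, int], int] = {}
        if config.attention_variant != "none":
            for point in INSERTION_POINTS:
                if point not in config.insertion_points:
                    continue
                n = 1 if config.placement == "per_layer" else self._stage_nblocks[point]
                for b in range(n):
                    self._att_index[(point, b)] = len(self.attention)
                    self.attention.append(MaskGuidedAttention(
                        self._stage_widths[point], config.mlp_reduction,
                        config.attention_variant, rng=rng))

    def n_attention_modules(self) -> int:
        return len(self.attention)

    def _enhance(self, h, mask, point, block_idx, last_in_stage):
        cfg = self.config
        if mask is None or cfg.attention_variant == "none":
            return h
        if cfg.placement == "per_layer":
            if last_in_stage and (point, 0) in self._att_index:
                h = self.attention[self._att_index[(point, 0)]](h, mask)
        else:
            key = (point, block_idx)
            if key in self._att_index:
                h = self.attention[self._att_index[key]](h, mask)
        return h

    def forward(self, x: Tensor, mask: Tensor | None = None):
        """Returns (logits, features); ``features`` maps each point to its
        stage output, enhanced where an attention block is configured."""
        features: dict[str, Tensor] = {}
        h = self.pool(ag.relu(self.stem_bn(self.stem_conv(as_tensor(x)))))
        h = self._enhance(h, mask, "L0", 0, True)
        features["L0"] = h
        for point, stage in (("L1", self.stage1), ("L2", self.stage2),
                             ("L3", self.stage3), ("L4", self.stage4)):
            n = len(stage)
            for i, blk in enumerate(stage):
                h = blk(h)
                h = self._enhance(h, mask, point, i, i == n - 1)
            features[point] = h
        pooled = h.mean(axis=(2, 3))
        return self.fc(pooled), features


class DualBranchModel(nn.Module):
    """Segmentation branch first, its probability map guiding the classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        if config.include_segmentation:
            self.segmentation = SegmentationBranch(config, rng=rng)
        else:
            self.segmentation = None
        self.classifier = ClassificationBackbone(config, rng=rng)

    def forward(self, images: Tensor, mask_override: Tensor | None = None) -> DualOutput:
        images = as_tensor(images)
        if images.ndim != 4 or images.shape[1] != 1:
            raise ValueError("expected a (B, 1, H, W) batch of grayscale images")
        if images.shape[-1] != self.config.input_size:
            raise ValueError(
                f"input size {images.shape[-1]} != configured {self.config.input_size}")
        seg_prob = None
        if self.segmentation is not None:
            seg_prob = self.segmentation(images)
        mask = mask_override if mask_override is not None else seg_prob
        use_mask = mask if self.config.attention_variant != "none" else None
        logits, enhanced = self.classifier(images, use_mask)
        return DualOutput(class_logits=logits, seg_prob=seg_prob,
                          enhanced_features=enhanced)


def build_segmentation_branch(config: ModelConfig, seed: int = 0) -> SegmentationBranch:
    return SegmentationBranch(config, rng=np.random.default_rng(seed))


def build_classification_backbone(config: ModelConfig, seed: int = 0) -> ClassificationBackbone:
    return ClassificationBackbone(config, rng=np.random.default_rng(seed))


def build_model(config: ModelConfig, seed: int = 0) -> DualBranchModel:
    return DualBranchModel(config, seed=seed)


def forward_dual(images, model: DualBranchModel) -> DualOutput:
    return model(images)
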