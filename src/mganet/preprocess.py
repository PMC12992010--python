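"""Field-of-view extraction for ultrasound frames.

Clinical ultrasound exports carry vendor text bands, measurement
overlays and black borders around the scanned tissue.  The pipeline
here isolates the tissue field and standardises it for the network:

1. adaptive (local-mean) thresholding separates bright tissue from the
   dark surround,
2. morphological opening-then-closing smooths the binary mask,
3. the largest connected foreground component is taken as tissue and
   the bounding rectangle of its convex hull becomes the crop window,
4. the crop is resized bilinearly to the network input size, and the
   lesion box is remapped into the resized frame with outward rounding.

The module is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_local
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing, convex_hull_image, footprint_rectangle, opening

from .autograd import interp_matrix
from .weak_labels import BBox

__all__ = [
    "CropResult",
    "binarize_adaptive",
    "clean_mask",
    "tissue_region",
    "crop_and_resize",
    "map_bbox",
    "preprocess_image",
]

DEFAULT_BLOCK_SIZE = 51
DEFAULT_OFFSET = 5.0
DEFAULT_KERNEL = 3
NETWORK_SIZE = 224


def auto_block_size(height: int, width: int) -> int:
    """Threshold neighbourhood scaled to the frame: roughly the width of the
    dark margin around the tissue field, capped at the full-size default."""
    return min(DEFAULT_BLOCK_SIZE, 2 * int(0.12 * min(height, width)) + 1)


@dataclass(frozen=True)
class CropResult:
    cropped_image: np.ndarray  # (target, target) float64
    crop_box: BBox  # in original-image coordinates
    scale: tuple[float, float]  # (s_x, s_y) from crop to network frame


def binarize_adaptive(image: np.ndarray, block_size: int = DEFAULT_BLOCK_SIZE,
                      offset: float = DEFAULT_OFFSET) -> np.ndarray:
    """Foreground where intensity exceeds the local mean by more than ``offset``."""
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError("block_size must be an odd integer >= 3")
    img = np.asarray(image, dtype=np.float64)
    # threshold_local returns (local mean - offset); a negative offset
    # therefore demands a positive margin above the local mean.
    thresh = threshold_local(img, block_size=block_size, method="mean", offset=-float(offset))
    return img > thresh


def clean_mask(binary_mask: np.ndarray, kernel_size: int = DEFAULT_KERNEL) -> np.ndarray:
    """Morphological opening then closing with a square structuring element."""
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    footprint = footprint_rectangle((kernel_size, kernel_size))
    mask = np.asarray(binary_mask, dtype=bool)
    return closing(opening(mask, footprint), footprint).astype(bool)


def tissue_region(binary_mask: np.ndarray) -> BBox:
    """Bounding rectangle of the convex hull of the largest foreground component."""
    mask = np.asarray(binary_mask, dtype=bool)
    labels = cc_label(mask, connectivity=2)  # 8-connectivity
    regions = regionprops(labels)
    if not regions:
        raise ValueError("no tissue found: mask has no foreground component")
    largest = max(regions, key=lambda r: r.area)
    hull = convex_hull_image(labels == largest.label)
    rows, cols = np.nonzero(hull)
    return BBox(x_min=int(cols.min()), y_min=int(rows.min()),
                x_max=int(cols.max()), y_max=int(rows.max()))


def _resize_bilinear_2d(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    Mh = interp_matrix(img.shape[0], out_h)
    Mw = interp_matrix(img.shape[1], out_w)
    return Mh @ img @ Mw.T


def crop_and_resize(image: np.ndarray, bbox: BBox,
                    target_size: int = NETWORK_SIZE) -> CropResult:
    """Crop to ``bbox`` (inclusive edges) and resize to a square network input."""
    h, w = image.shape[:2]
    if not (0 <= bbox.x_min <= bbox.x_max < w and 0 <= bbox.y_min <= bbox.y_max < h):
        raise ValueError("bbox must lie within the image")
    if bbox.width < 2 or bbox.height < 2:
        raise ValueError("degenerate crop box")
    crop = np.asarray(image, dtype=np.float64)[bbox.y_min:bbox.y_max + 1,
                                               bbox.x_min:bbox.x_max + 1]
    resized = _resize_bilinear_2d(crop, target_size, target_size)
    return CropResult(cropped_image=resized, crop_box=bbox,
                      scale=(target_size / bbox.width, target_size / bbox.height))


def map_bbox(bbox: BBox, crop: CropResult, target_size: int = NETWORK_SIZE) -> BBox:
    """Translate a box into crop coordinates, apply the resize scale, round
    outward (floor minima, ceil maxima) and clip to the network frame."""
    cb = crop.crop_box
    if bbox.x_max < cb.x_min or bbox.x_min > cb.x_max or \
            bbox.y_max < cb.y_min or bbox.y_min > cb.y_max:
        raise ValueError("bbox lies entirely outside the crop window")
    sx, sy = crop.scale
    x_min = math.floor((bbox.x_min - cb.x_min) * sx)
    y_min = math.floor((bbox.y_min - cb.y_min) * sy)
    x_max = math.ceil((bbox.x_max - cb.x_min) * sx)
    y_max = math.ceil((bbox.y_max - cb.y_min) * sy)
    return BBox(x_min=x_min, y_min=y_min, x_max=x_max, y_max=y_max).clipped(
        target_size, target_size)


def preprocess_image(image: np.ndarray, bbox: BBox | None = None,
                     target_size: int = NETWORK_SIZE,
                     block_size: int | None = None,
                     offset: float = DEFAULT_OFFSET,
                     kernel_size: int = DEFAULT_KERNEL) -> tuple[CropResult, BBox | None]:
    """Full pipeline: threshold, smooth, locate tissue, crop+resize, remap box."""
    if block_size is None:
        block_size = auto_block_size(*image.shape[:2])
    mask = clean_mask(binarize_adaptive(image, block_size, offset), kernel_size)
    region = tissue_region(mask)
    crop = crop_and_resize(image, region, target_size)
    mapped = map_bbox(bbox, crop, target_size) if bbox is not None else None
    return crop, mapped
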