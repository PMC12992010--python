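"""Elliptical pseudo-segmentation labels from detection boxes.

Pixel-accurate lesion masks are expensive to annotate; bounding boxes
are cheap.  The weak-supervision strategy inscribes an ellipse in each
box and uses its binary raster as the segmentation target: with box
corners (x_min, y_min) and (x_max, y_max),

    center     (x_c, y_c) = ((x_min + x_max) / 2, (y_min + y_max) / 2)
    semi-axes  (a, b)     = ((x_max - x_min) / 2, (y_max - y_min) / 2)
    mask(i, j) = 1  iff  (j - x_c)^2 / a^2 + (i - y_c)^2 / b^2 <= 1

evaluated at integer pixel indices (i row, j column), boundary
included.  Center and semi-axes are kept as exact floats; nothing is
rounded before the inequality is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BBox", "bbox_to_ellipse_mask"]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in pixel coordinates, edges inclusive.

    ``x`` indexes columns, ``y`` rows (0-based).
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def semi_axes(self) -> tuple[float, float]:
        return ((self.x_max - self.x_min) / 2.0, (self.y_max - self.y_min) / 2.0)

    def contains(self, row: int, col: int) -> bool:
        return self.y_min <= row <= self.y_max and self.x_min <= col <= self.x_max

    def clipped(self, height: int, width: int) -> "BBox":
        return BBox(x_min=max(0, self.x_min), y_min=max(0, self.y_min),
                    x_max=min(width - 1, self.x_max), y_max=min(height - 1, self.y_max))


def bbox_to_ellipse_mask(bbox: BBox, height: int, width: int) -> np.ndarray:
    """Rasterise the ellipse inscribed in ``bbox`` on an H x W grid.

    Returns a uint8 array with 1 inside (boundary included) and 0
    outside.  Degenerate boxes (zero semi-axis) and boxes that leave the
    image raise ``ValueError``.
    """
    xc, yc = bbox.center
    a, b = bbox.semi_axes
    if a <= 0 or b <= 0:
        raise ValueError(f"degenerate box: semi-axes ({a}, {b}) must be positive")
    if bbox.x_min < 0 or bbox.y_min < 0 or bbox.x_max >= width or bbox.y_max >= height:
        raise ValueError("bounding box lies outside the image")
    i = np.arange(height, dtype=np.float64)[:, None]
    j = np.arange(width, dtype=np.float64)[None, :]
    inside = ((j - xc) ** 2 / a ** 2 + (i - yc) ** 2 / b ** 2) <= 1.0
    return inside.astype(np.uint8)
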