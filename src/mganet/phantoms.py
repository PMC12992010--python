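"""Synthetic ultrasound-style phantoms with nodule annotations.

Real thyroid ultrasound frames cannot be redistributed, so this module
fabricates grayscale images that reproduce the properties the rest of
the pipeline depends on: a speckle-textured tissue field surrounded by
a black margin, a single hypoechoic (darker-than-tissue) nodule whose
shape statistics differ by class, a tight bounding-box annotation, and
an optional text band or dark border that the preprocessing stage must
strip.  The class-conditional geometry encodes the standard clinical
shape cue: benign nodules are rendered wider-than-tall with smooth
elliptical margins, malignant nodules taller-than-wide with irregular
margins and bright calcification specks.

Everything is a pure function of an explicit integer seed; regenerating
a sample from its spec is byte-identical.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .weak_labels import BBox

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "render_background",
    "render_nodule",
    "generate_sample",
    "generate_dataset",
    "load_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["path", "x_min", "y_min", "x_max", "y_max", "label", "split"]

# mean gray level of the tissue field and amplitude of its slow spatial drift
_TISSUE_LEVEL = 150.0
_TISSUE_DRIFT = 18.0
# tissue rectangle as fractions of the image (rows then cols); the region
# outside it is black, emulating the unscanned margin of an ultrasound frame
_TISSUE_FRAC = (0.12, 0.80, 0.12, 0.88)
_BAND_FRAC = 0.88  # text band starts here when decoration == "text_band"
_SPECK_VALUE = 235.0
# speckle grains in real ultrasound span several pixels; this sigma sets the
# correlation length of the multiplicative noise field
_SPECKLE_GRAIN_SIGMA = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one phantom; rendering is deterministic in it."""

    image_height: int
    image_width: int
    class_label: str  # "benign" | "malignant"
    nodule_center: tuple[int, int]  # (row, col)
    semi_axes: tuple[float, float]  # (a_x, a_y) in pixels
    boundary_irregularity: float
    n_specks: int
    nodule_intensity_drop: float
    speckle_scale: float
    decoration: str = "none"  # "none" | "text_band" | "dark_border"
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in ("benign", "malignant"):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.decoration not in ("none", "text_band", "dark_border"):
            raise ValueError(f"unknown decoration {self.decoration!r}")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if not 0 <= self.nodule_intensity_drop < 1:
            raise ValueError("nodule_intensity_drop must be in [0, 1)")


@dataclass
class PhantomSample:
    image: np.ndarray  # uint8 (H, W)
    bbox: BBox
    label: int  # 0 benign, 1 malignant
    nodule_pixels: np.ndarray  # bool (H, W), True inside the nodule
    spec: PhantomSpec


def tissue_rect(height: int, width: int) -> BBox:
    """Ground-truth rectangle of the scanned tissue field (inclusive edges)."""
    r0, r1, c0, c1 = _TISSUE_FRAC
    return BBox(x_min=int(c0 * width), y_min=int(r0 * height),
                x_max=int(c1 * width) - 1, y_max=int(r1 * height) - 1)


def render_background(height: int, width: int, speckle_scale: float,
                      seed: int) -> np.ndarray:
    """Speckled tissue field: smooth low-frequency drift times a positive
    unit-mean noise field, clipped to [0, 255] and quantised to uint8."""
    if height <= 0 or width <= 0:
        raise ValueError("image dimensions must be positive")
    rng = np.random.default_rng(seed)
    drift = gaussian_filter(rng.standard_normal((height, width)),
                            sigma=max(height, width) / 8.0, mode="reflect")
    sd = drift.std()
    if sd > 0:
        drift = drift / sd
    field = _TISSUE_LEVEL + _TISSUE_DRIFT * drift
    grains = gaussian_filter(rng.standard_normal((height, width)),
                             sigma=_SPECKLE_GRAIN_SIGMA, mode="reflect")
    gsd = grains.std()
    if gsd > 0:
        grains = grains / gsd
    noise = np.maximum(0.0, 1.0 + speckle_scale * grains)
    img = np.clip(field * noise, 0.0, 255.0)
    return img.astype(np.uint8)


def _boundary_modulation(theta: np.ndarray, irregularity: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Smooth periodic radial perturbation with |modulation - 1| <= irregularity."""
    if irregularity == 0:
        return np.ones_like(theta)
    harmonics = (2, 3, 4)
    coefs = rng.normal(size=(len(harmonics), 2))
    norm = np.abs(coefs).sum()
    wave = np.zeros_like(theta)
    for (c, s), k in zip(coefs, harmonics):
        wave += c * np.cos(k * theta) + s * np.sin(k * theta)
    return 1.0 + irregularity * wave / norm


def render_nodule(image: np.ndarray, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Darken the (possibly radially perturbed) ellipse interior and stamp
    bright specks; returns the new image and the exact interior pixel mask."""
    h, w = image.shape
    cy, cx = spec.nodule_center
    ax, ay = spec.semi_axes
    reach = max(ax, ay) * (1.0 + spec.boundary_irregularity)
    if (cy - reach < 0 or cy + reach > h - 1 or cx - reach < 0 or cx + reach > w - 1):
        raise ValueError("nodule (with perturbation) extends outside the image")
    rng = np.random.default_rng(spec.seed + 1)
    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - float(cy)
    dx = cols - float(cx)
    theta = np.arctan2(dy, dx)
    mod = _boundary_modulation(theta, spec.boundary_irregularity, rng)
    inside = (dx / (ax * mod)) ** 2 + (dy / (ay * mod)) ** 2 <= 1.0
    out = image.astype(np.float64)
    out[inside] *= 1.0 - spec.nodule_intensity_drop
    if spec.n_specks > 0:
        ii, jj = np.nonzero(inside)
        picks = rng.choice(len(ii), size=min(spec.n_specks, len(ii)), replace=False)
        for p in picks:
            r0, r1 = max(ii[p] - 1, 0), min(ii[p] + 2, h)
            c0, c1 = max(jj[p] - 1, 0), min(jj[p] + 2, w)
            block = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            block |= inside[r0:r1, c0:c1]
            out[r0:r1, c0:c1][block] = _SPECK_VALUE
    return np.clip(out, 0, 255).astype(np.uint8), inside


def _draw_spec(class_label: str, size: int, seed: int,
               decoration: str, speckle_scale: float | None) -> PhantomSpec:
    rng = np.random.default_rng(seed)
    rect = tissue_rect(size, size)
    ctr_r = (rect.y_min + rect.y_max) / 2.0  # nodule stays well inside the field
    ctr_c = (rect.x_min + rect.x_max) / 2.0
    cy = int(round(ctr_r + rng.uniform(-0.06, 0.06) * size))
    cx = int(round(ctr_c + rng.uniform(-0.08, 0.08) * size))
    long_axis = rng.uniform(0.14, 0.19) * size
    ratio = rng.uniform(0.55, 0.70)  # short/long, bounded away from 1 so the
    # aspect cue survives boundary perturbation and pixel quantisation
    if class_label == "benign":
        ax, ay = long_axis, long_axis * ratio
        irregularity, n_specks = 0.0, 0
    else:
        ax, ay = long_axis * ratio, long_axis
        irregularity = rng.uniform(0.03, 0.06)
        n_specks = int(rng.integers(3, 9))
    return PhantomSpec(
        image_height=size, image_width=size, class_label=class_label,
        nodule_center=(cy, cx), semi_axes=(ax, ay),
        boundary_irregularity=irregularity, n_specks=n_specks,
        nodule_intensity_drop=rng.uniform(0.35, 0.55),
        speckle_scale=speckle_scale if speckle_scale is not None
        else rng.uniform(0.18, 0.30),
        decoration=decoration, seed=seed,
    )


def _stamp_decoration(image: np.ndarray, decoration: str, seed: int) -> np.ndarray:
    h, w = image.shape
    out = image.copy()
    if decoration == "text_band":
        band_top = int(_BAND_FRAC * h)
        out[band_top:, :] = 0
        rng = np.random.default_rng(seed + 2)
        # glyph-like bright dashes, small and mutually separated
        n_glyphs = max(3, w // 16)
        for _ in range(n_glyphs):
            r = int(rng.integers(band_top + 2, h - 2))
            c = int(rng.integers(2, w - 5))
            out[r:r + 1, c:c + 3] = 255
    elif decoration == "dark_border":
        t = max(2, h // 24)
        out[:t, :] = 0
        out[-t:, :] = 0
        out[:, :t] = 0
        out[:, -t:] = 0
    return out


def tight_bbox(pixel_mask: np.ndarray) -> BBox:
    ii, jj = np.nonzero(pixel_mask)
    if len(ii) == 0:
        raise ValueError("empty pixel set has no bounding box")
    return BBox(x_min=int(jj.min()), y_min=int(ii.min()),
                x_max=int(jj.max()), y_max=int(ii.max()))


def render_sample(spec: PhantomSpec) -> PhantomSample:
    """Render a full sample from its spec (deterministic, byte-identical)."""
    h, w = spec.image_height, spec.image_width
    tissue = render_background(h, w, spec.speckle_scale, spec.seed)
    img = np.zeros((h, w), dtype=np.uint8)
    rect = tissue_rect(h, w)
    img[rect.y_min:rect.y_max + 1, rect.x_min:rect.x_max + 1] = \
        tissue[rect.y_min:rect.y_max + 1, rect.x_min:rect.x_max + 1]
    img, nodule = render_nodule(img, spec)
    img = _stamp_decoration(img, spec.decoration, spec.seed)
    return PhantomSample(image=img, bbox=tight_bbox(nodule),
                         label=0 if spec.class_label == "benign" else 1,
                         nodule_pixels=nodule, spec=spec)


def generate_sample(class_label: str, size: int, seed: int,
                    decoration: str = "none",
                    speckle_scale: float | None = None) -> PhantomSample:
    """Draw a class-conditional spec from seeded ranges and render it."""
    if size < 32:
        raise ValueError("size must be >= 32")
    spec = _draw_spec(class_label, size, seed, decoration, speckle_scale)
    return render_sample(spec)


def generate_dataset(n_per_class: int, size: int, seed: int, out_dir,
                     train_frac: float = 0.7, decoration: str = "none") -> Path:
    """Write PNGs plus a CSV manifest; returns the manifest path.

    Splitting is stratified: per class the first ``floor(train_frac * n)``
    samples (in generation order) are 'train', the rest 'val'.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    n_train = math.floor(train_frac * n_per_class)
    for label_name in ("benign", "malignant"):
        child_seeds = rng.integers(0, 2**31 - 1, size=n_per_class)
        for i, s in enumerate(child_seeds):
            sample = generate_sample(label_name, size, int(s), decoration)
            fname = f"{label_name}_{i:04d}.png"
            Image.fromarray(sample.image).save(out_dir / fname)
            rows.append([fname, sample.bbox.x_min, sample.bbox.y_min,
                         sample.bbox.x_max, sample.bbox.y_max, sample.label,
                         "train" if i < n_train else "val"])
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest


def load_manifest(manifest_path) -> list[dict]:
    """Read a manifest CSV into a list of records with typed fields."""
    manifest_path = Path(manifest_path)
    records = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            records.append({
                "path": manifest_path.parent / row["path"],
                "bbox": BBox(int(row["x_min"]), int(row["y_min"]),
                             int(row["x_max"]), int(row["y_max"])),
                "label": int(row["label"]),
                "split": row["split"],
            })
    return records
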