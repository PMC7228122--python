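"""Region-of-interest cropping, timestamp removal, and augmentation.

Otoscope frames come with a black circular-aperture border and a burned-in
timestamp at the bottom right.  The preprocessing front end (1) binarizes
the image and finds the bounding box of the bright content, (2) crops to
that box, and (3) zero-fills the fixed bottom-right timestamp region.
Augmentation applies a random affine transform (flips, rotation, scale,
shear, translation) drawn from fixed ranges; it is used to oversample
minority classes to a balanced training set.

Order of operations for a training image: margin crop, then timestamp
removal, then (training only) augmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import laplace
from skimage.transform import warp

from .images import LabeledImage

#: Default binarization threshold (of 255) separating content from the
#: black border. JPEG-compressed borders are near-zero but not exactly
#: zero, so a small fixed threshold is used rather than Otsu (which is
#: unstable on mostly-dark images).
DEFAULT_THRESHOLD = 10

#: Default timestamp removal region: bottom 8% of height, right 25% of width.
DEFAULT_TS_HEIGHT_FRAC = 0.08
DEFAULT_TS_WIDTH_FRAC = 0.25


@dataclass(frozen=True)
class ROIBox:
    """Half-open pixel box ``[row_start, row_stop) x [col_start, col_stop)``, 0-based."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop):
            raise ValueError(f"invalid row range [{self.row_start}, {self.row_stop})")
        if not (0 <= self.col_start < self.col_stop):
            raise ValueError(f"invalid col range [{self.col_start}, {self.col_stop})")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start


@dataclass(frozen=True)
class AugmentationSpec:
    """Ranges for the random affine augmentation.

    ``rotation_degrees`` is the width of the uniform rotation range
    starting at 0 (360 = uniform over the full circle).  Scale is uniform
    in [scale_min, scale_max], shear (applied independently on both axes)
    uniform in [shear_min, shear_max] degrees, translation (both axes)
    uniform integer pixels in [translate_min, translate_max].
    """

    reflect_horizontal: bool = True
    reflect_vertical: bool = True
    rotation_degrees: float = 360.0
    scale_min: float = 0.7
    scale_max: float = 2.0
    shear_min: float = 0.0
    shear_max: float = 45.0
    translate_min: int = -30
    translate_max: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_min > self.scale_max or self.scale_min <= 0:
            raise ValueError("require 0 < scale_min <= scale_max")
        if not (0.0 <= self.shear_min <= self.shear_max <= 45.0):
            raise ValueError("shear range must lie within [0, 45] degrees")
        if not (-30 <= self.translate_min <= self.translate_max <= 30):
            raise ValueError("translation range must lie within [-30, 30] pixels")
        if self.rotation_degrees < 0:
            raise ValueError("rotation_degrees must be >= 0")


#: Spec with every range degenerate: augmentation becomes the identity.
IDENTITY_AUGMENTATION = AugmentationSpec(
    reflect_horizontal=False,
    reflect_vertical=False,
    rotation_degrees=0.0,
    scale_min=1.0,
    scale_max=1.0,
    shear_min=0.0,
    shear_max=0.0,
    translate_min=0,
    translate_max=0,
)


@dataclass(frozen=True)
class TransformParams:
    """One concrete affine transform drawn from an :class:`AugmentationSpec`."""

    flip_horizontal: bool
    flip_vertical: bool
    rotation_deg: float
    scale: float
    shear_h_deg: float
    shear_v_deg: float
    translate_x: int
    translate_y: int

    @property
    def is_identity(self) -> bool:
        return (
            not self.flip_horizontal
            and not self.flip_vertical
            and self.rotation_deg == 0.0
            and self.scale == 1.0
            and self.shear_h_deg == 0.0
            and self.shear_v_deg == 0.0
            and self.translate_x == 0
            and self.translate_y == 0
        )


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 grayscale luminance of an RGB raster, float in [0, 255]."""
    px = np.asarray(pixels, dtype=np.float64)
    return 0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2]


def find_roi(image: LabeledImage, threshold: float = DEFAULT_THRESHOLD) -> ROIBox:
    """Bounding box of all pixels with luminance above ``threshold``.

    Scans for the first and last foreground row and column; raises
    ``ValueError`` if the image has no pixel above the threshold.
    """
    mask = luminance(image.pixels) > threshold
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("no foreground: every pixel is at or below the threshold")
    return ROIBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def crop_roi(image: LabeledImage, box: ROIBox) -> LabeledImage:
    """Crop to ``box``; label and id are preserved, pixels copied unchanged."""
    if box.row_stop > image.height or box.col_stop > image.width:
        raise ValueError(f"box {box} exceeds image extent {image.height}x{image.width}")
    return image.with_pixels(
        image.pixels[box.row_start : box.row_stop, box.col_start : box.col_stop].copy()
    )


def remove_timestamp(
    image: LabeledImage,
    region_height_frac: float = DEFAULT_TS_HEIGHT_FRAC,
    region_width_frac: float = DEFAULT_TS_WIDTH_FRAC,
) -> LabeledImage:
    """Zero-fill the bottom-right timestamp region.

    The region spans the bottom ``region_height_frac`` of rows and the
    right ``region_width_frac`` of columns.  Zero-filling (rather than
    cropping) preserves image geometry; the operation is idempotent.
    """
    for frac in (region_height_frac, region_width_frac):
        if not (0.0 < frac <= 0.5):
            raise ValueError(f"region fraction {frac} outside (0, 0.5]")
    px = image.pixels.copy()
    h = max(1, int(round(region_height_frac * image.height)))
    w = max(1, int(round(region_width_frac * image.width)))
    px[image.height - h :, image.width - w :, :] = 0
    return image.with_pixels(px)


def blur_score(image: LabeledImage) -> float:
    """Sharpness estimate: variance of the Laplacian of the luminance.

    Higher means sharper.  Offered for optional quality screening of
    query/validation images; nothing in the pipeline applies a
    threshold automatically.
    """
    gray = luminance(image.pixels) / 255.0
    return float(laplace(gray).var())


def sample_transform(
    spec: AugmentationSpec, rng: np.random.Generator
) -> TransformParams:
    """Draw one affine transform from the spec's ranges."""
    flip_h = bool(spec.reflect_horizontal and rng.integers(2))
    flip_v = bool(spec.reflect_vertical and rng.integers(2))
    rotation = float(rng.uniform(0.0, spec.rotation_degrees)) if spec.rotation_degrees else 0.0
    scale = float(rng.uniform(spec.scale_min, spec.scale_max))
    shear_h = float(rng.uniform(spec.shear_min, spec.shear_max))
    shear_v = float(rng.uniform(spec.shear_min, spec.shear_max))
    tx = int(rng.integers(spec.translate_min, spec.translate_max + 1))
    ty = int(rng.integers(spec.translate_min, spec.translate_max + 1))
    return TransformParams(flip_h, flip_v, rotation, scale, shear_h, shear_v, tx, ty)


def _affine_matrix(params: TransformParams, height: int, width: int) -> np.ndarray:
    """Homogeneous 3x3 forward matrix in (x, y) coordinates, about the image center."""
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0

    def mat(a, b, c, d, tx=0.0, ty=0.0):
        return np.array([[a, b, tx], [c, d, ty], [0.0, 0.0, 1.0]])

    m = mat(1, 0, 0, 1)
    if params.flip_horizontal:
        m = mat(-1, 0, 0, 1) @ m
    if params.flip_vertical:
        m = mat(1, 0, 0, -1) @ m
    th = math.radians(params.rotation_deg)
    m = mat(math.cos(th), -math.sin(th), math.sin(th), math.cos(th)) @ m
    m = mat(params.scale, 0, 0, params.scale) @ m
    m = mat(1, math.tan(math.radians(params.shear_h_deg)), 0, 1) @ m
    m = mat(1, 0, math.tan(math.radians(params.shear_v_deg)), 1) @ m
    m = mat(1, 0, 0, 1, params.translate_x, params.translate_y) @ m
    to_center = mat(1, 0, 0, 1, -cx, -cy)
    from_center = mat(1, 0, 0, 1, cx, cy)
    return from_center @ m @ to_center


def apply_transform(pixels: np.ndarray, params: TransformParams) -> np.ndarray:
    """Apply one affine transform; bilinear resampling, black fill, same shape."""
    if params.is_identity:
        return pixels.copy()
    h, w = pixels.shape[:2]
    inverse = np.linalg.inv(_affine_matrix(params, h, w))
    out = warp(
        pixels.astype(np.float64),
        inverse_map=inverse,
        output_shape=pixels.shape,
        order=1,
        cval=0.0,
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def augment(
    image: LabeledImage,
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> LabeledImage:
    """Apply one random affine transform drawn from ``spec``.

    With ``rng=None`` the generator is seeded from ``spec.seed``, so two
    calls with the same image and spec produce identical outputs.  Label
    and id are never changed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = sample_transform(spec, rng)
    return image.with_pixels(apply_transform(image.pixels, params))


def balance_classes(
    images: list[LabeledImage],
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> list[LabeledImage]:
    """Equalize class counts by augmenting resampled minority-class images.

    Majority-class images pass through unchanged; each minority class is
    topped up with augmented copies of randomly resampled members (with
    replacement).  Augmented copies get ids ``<orig>-aug<i>``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[LabeledImage]] = {}
    for img in images:
        by_class.setdefault(img.label, []).append(img)
    if any(len(v) == 0 for v in by_class.values()) or not by_class:
        raise ValueError("every class must have at least one image")
    target = max(len(v) for v in by_class.values())
    out = list(images)
    for label in sorted(by_class):
        members = by_class[label]
        for i in range(target - len(members)):
            src = members[int(rng.integers(len(members)))]
            aug = augment(src, spec, rng)
            out.append(LabeledImage(aug.pixels, label, f"{src.id}-aug{i}"))
    return out
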