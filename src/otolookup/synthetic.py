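"""Synthetic otoscopy-like image generation.

Real otoscope frames show a bright, roughly elliptical eardrum region
surrounded by the black margin of the scope aperture, with a timestamp
burned into the bottom-right corner.  The three diagnostic categories
differ mainly in color (effusion: warm amber; normal: pink/gray) while
tympanostomy tubes add a small, visually distinctive high-contrast
structure.

This module emulates exactly that structure with three color/texture
separable classes so the whole pipeline is testable without any image
download:

* class ``effusion`` — warm/amber drum;
* class ``normal``   — pink drum;
* class ``tube``     — desaturated gray-blue drum plus a small bright
  ellipse (the "tube"), whose contrast scales with separability.

A ``separability`` knob interpolates the class palettes between one
shared hue distribution (0.0: classes are statistically identical) and
fully disjoint hue ranges (1.0).  The generator records its ground truth
(the inner content box and the timestamp block), enabling exact
round-trip tests of the preprocessing stage: every pixel outside the
inner box is exactly 0, and the drum ellipse is inscribed in the inner
box so its bounding box *is* the inner box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

from .images import CLASSES, LabeledImage
from .preprocess import ROIBox

# Class palettes at separability 1.0: hue (in [0,1)), saturation.
_CLASS_HUE = {"effusion": 0.07, "normal": 0.93, "tube": 0.55}
_CLASS_SAT = {"effusion": 0.60, "normal": 0.40, "tube": 0.18}
# Shared palette used at separability 0.0.
_SHARED_HUE = 0.07
_SHARED_SAT = 0.45
_HUE_JITTER = 0.01
_SAT_JITTER = 0.03
_BASE_VALUE = 0.62
_VALUE_JITTER = 0.05
_TEXTURE_AMPLITUDE = 0.06


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dataset.

    ``separability`` in [0, 1] interpolates between identical class color
    distributions (0) and disjoint hue ranges (1).  ``margin_fraction``
    in [0, 0.4] sets the black border thickness as a fraction of the
    smaller image dimension.  ``blur_sigma > 0`` optionally blurs the
    drum content (for quality-sensitivity experiments); it never touches
    the black margin.
    """

    n_per_class: int
    image_height: int = 96
    image_width: int = 128
    separability: float = 1.0
    margin_fraction: float = 0.1
    timestamp: bool = True
    seed: int = 0
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image dimensions must be >= 8")
        if not (0.0 <= self.separability <= 1.0):
            raise ValueError("separability must lie in [0, 1]")
        if not (0.0 <= self.margin_fraction <= 0.4):
            raise ValueError("margin_fraction must lie in [0, 0.4]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


def inner_box(spec: SynthSpec) -> ROIBox:
    """Ground-truth content box: everything outside it is exactly black."""
    m = int(round(spec.margin_fraction * min(spec.image_height, spec.image_width)))
    return ROIBox(m, spec.image_height - m, m, spec.image_width - m)


def timestamp_box(spec: SynthSpec) -> ROIBox:
    """Ground-truth timestamp block, in full-image coordinates.

    The block sits inside the inner box, within the bottom 8% x right 25%
    region of the box, so the preprocess module's default removal region
    covers it exactly after cropping.
    """
    box = inner_box(spec)
    ts_h = max(2, int(0.05 * box.height))
    ts_w = max(4, int(0.18 * box.width))
    inset = int(0.02 * box.width)
    return ROIBox(
        box.row_stop - ts_h,
        box.row_stop,
        box.col_stop - inset - ts_w,
        box.col_stop - inset,
    )


def class_palette(label: str, separability: float) -> tuple[float, float]:
    """(hue, saturation) center for a class at a given separability."""
    s = separability
    hue = (1.0 - s) * _SHARED_HUE + s * _CLASS_HUE[label]
    sat = (1.0 - s) * _SHARED_SAT + s * _CLASS_SAT[label]
    return hue, sat


def _render_image(spec: SynthSpec, label: str, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.image_height, spec.image_width
    box = inner_box(spec)
    bh, bw = box.height, box.width

    # Drum ellipse inscribed in the inner box: it is tangent to all four
    # sides, so its luminance bounding box equals the box exactly.
    cy = (box.row_start + box.row_stop) / 2.0
    cx = (box.col_start + box.col_stop) / 2.0
    rows = np.arange(box.row_start, box.row_stop) + 0.5
    cols = np.arange(box.col_start, box.col_stop) + 0.5
    yn = (rows[:, None] - cy) / (bh / 2.0)
    xn = (cols[None, :] - cx) / (bw / 2.0)
    drum = yn**2 + xn**2 <= 1.0

    hue_c, sat_c = class_palette(label, spec.separability)
    hue = (hue_c + rng.normal(0.0, _HUE_JITTER)) % 1.0
    sat = float(np.clip(sat_c + rng.normal(0.0, _SAT_JITTER), 0.0, 1.0))
    value_base = _BASE_VALUE + rng.normal(0.0, _VALUE_JITTER)

    # Low-frequency brightness texture over the drum.
    noise = rng.standard_normal((bh, bw))
    sigma = max(2.0, min(bh, bw) / 12.0)
    field = gaussian_filter(noise, sigma=sigma)
    sd = field.std()
    if sd > 0:
        field = field / sd * _TEXTURE_AMPLITUDE

    hsv = np.zeros((bh, bw, 3))
    hsv[..., 0] = hue
    hsv[..., 1] = sat
    hsv[..., 2] = np.clip(value_base + field, 0.25, 1.0)

    if label == "tube":
        # Small bright low-saturation ellipse; contrast scales with
        # separability so classes stay indistinguishable at 0.
        blend = spec.separability
        if blend > 0:
            ty = cy + rng.uniform(-0.15, 0.15) * bh - box.row_start
            tx = cx + rng.uniform(-0.15, 0.15) * bw - box.col_start
            ry, rx = 0.12 * bh, 0.10 * bw
            yy = (np.arange(bh)[:, None] + 0.5 - ty) / ry
            xx = (np.arange(bw)[None, :] + 0.5 - tx) / rx
            tube_mask = yy**2 + xx**2 <= 1.0
            hsv[tube_mask, 1] = (1 - blend) * hsv[tube_mask, 1] + blend * 0.05
            hsv[tube_mask, 2] = (1 - blend) * hsv[tube_mask, 2] + blend * 0.98

    content = hsv2rgb(hsv)
    content[~drum] = 0.0
    if spec.blur_sigma > 0:
        content = gaussian_filter(content, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
        content[~drum] = np.minimum(content[~drum], 0.0)  # keep outside-drum black

    img = np.zeros((H, W, 3))
    img[box.row_start : box.row_stop, box.col_start : box.col_stop] = content

    if spec.timestamp:
        ts = timestamp_box(spec)
        img[ts.row_start : ts.row_stop, ts.col_start : ts.col_stop] = 1.0

    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def generate_dataset(spec: SynthSpec) -> list[LabeledImage]:
    """Generate ``3 * n_per_class`` labeled images, deterministically.

    Images are produced class-major in the canonical class order with ids
    ``<label>-<index>``; the same spec (including seed) always yields a
    bit-identical image set.
    """
    rng = np.random.default_rng(spec.seed)
    images = []
    for label in CLASSES:
        for i in range(spec.n_per_class):
            px = _render_image(spec, label, rng)
            images.append(LabeledImage(px, label, f"{label}-{i:03d}"))
    return images
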