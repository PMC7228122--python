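"""Handcrafted CBIR baseline features and KNN/SVM score tables.

The baseline descriptor concatenates four classic feature families:

    f1 = [ HSV histogram | color autocorrelogram |
           first two color moments per RGB channel | Gabor wavelet stats ]

and retrieval proceeds exactly as for the deep pipeline, except that the
C-dimensional class-score vectors come from a fitted KNN or SVM
classifier instead of a CNN's FC layer.  Scoring training images through
the classifier yields a lookup table structurally identical to the deep
one, so the same retrieve/evaluate machinery applies to both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import gabor_kernel
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .images import LabeledImage
from .retrieval import LookupTable


@dataclass(frozen=True)
class HandcraftedConfig:
    """Feature-family parameters.

    Defaults: 8x2x2 joint HSV histogram; autocorrelogram over 64
    uniformly quantized RGB colors at chessboard distances {1,3,5,7};
    Gabor bank of 4 scales x 6 orientations.  None of these values is
    dictated by the method itself; they are the common CBIR choices.
    """

    hsv_bins: tuple[int, int, int] = (8, 2, 2)
    correlogram_distances: tuple[int, ...] = (1, 3, 5, 7)
    correlogram_levels: int = 64
    gabor_scales: int = 4
    gabor_orientations: int = 6

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.hsv_bins):
            raise ValueError("hsv_bins must be positive")
        if self.correlogram_levels < 2:
            raise ValueError("correlogram_levels must be >= 2")
        if any(d < 1 for d in self.correlogram_distances):
            raise ValueError("correlogram distances must be >= 1")
        if self.gabor_scales < 1 or self.gabor_orientations < 1:
            raise ValueError("gabor bank dimensions must be positive")

    @property
    def total_length(self) -> int:
        return (
            int(np.prod(self.hsv_bins))
            + self.correlogram_levels * len(self.correlogram_distances)
            + 6
            + 2 * self.gabor_scales * self.gabor_orientations
        )


@dataclass(frozen=True)
class HandcraftedVector:
    """Concatenated feature vector with the span of each family recorded."""

    values: np.ndarray
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "values", v)

    def segment(self, name: str) -> np.ndarray:
        a, b = self.segments[name]
        return self.values[a:b]


def _as_pixels(image) -> np.ndarray:
    px = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if px.size == 0:
        raise ValueError("empty image")
    return px


def hsv_histogram(image, bins: tuple[int, int, int] = (8, 2, 2)) -> np.ndarray:
    """Joint HSV histogram, L1-normalized to sum 1."""
    px = _as_pixels(image)
    hsv = rgb2hsv(px).reshape(-1, 3)
    hist, _ = np.histogramdd(hsv, bins=bins, range=[(0, 1), (0, 1), (0, 1)])
    return (hist / hist.sum()).ravel()


def quantize_colors(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Uniform RGB quantization into ``levels`` colors (levels must be a cube)."""
    q = round(levels ** (1 / 3))
    if q**3 != levels:
        raise ValueError(f"correlogram levels must be a perfect cube, got {levels}")
    if levels > 256**3:
        raise ValueError("levels exceeds representable colors")
    idx = (pixels.astype(np.int64) * q) // 256
    return idx[..., 0] * q * q + idx[..., 1] * q + idx[..., 2]


def _ring_offsets(d: int) -> list[tuple[int, int]]:
    """All offsets at exact chessboard (L∞) distance d."""
    offs = []
    for dy in range(-d, d + 1):
        for dx in range(-d, d + 1):
            if max(abs(dy), abs(dx)) == d:
                offs.append((dy, dx))
    return offs


def color_autocorrelogram(
    image,
    distances: tuple[int, ...] = (1, 3, 5, 7),
    levels: int = 64,
) -> np.ndarray:
    """P(pixel at chessboard distance d has color c | pixel has color c).

    Colors are uniformly quantized; neighbors outside the image are
    excluded from the denominator.  Output is ordered color-major,
    distance-minor, with 0 where a color does not occur.
    """
    px = _as_pixels(image)
    q = quantize_colors(px, levels)
    h, w = q.shape
    out = np.zeros((levels, len(distances)))
    for di, d in enumerate(distances):
        same = np.zeros(levels)
        total = np.zeros(levels)
        for dy, dx in _ring_offsets(d):
            y0, y1 = max(0, -dy), min(h, h - dy)
            x0, x1 = max(0, -dx), min(w, w - dx)
            if y0 >= y1 or x0 >= x1:
                continue
            a = q[y0:y1, x0:x1].ravel()
            b = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx].ravel()
            total += np.bincount(a, minlength=levels)
            same += np.bincount(a[a == b], minlength=levels)
        nz = total > 0
        out[nz, di] = same[nz] / total[nz]
    return out.ravel()


def color_moments(image) -> np.ndarray:
    """(meanR, stdR, meanG, stdG, meanB, stdB); population std."""
    px = _as_pixels(image).astype(np.float64).reshape(-1, 3)
    return np.column_stack([px.mean(axis=0), px.std(axis=0)]).ravel()


def gabor_frequencies(scales: int) -> list[float]:
    """Geometrically spaced center frequencies from 0.4 down to 0.1 cycles/px."""
    if scales == 1:
        return [0.4]
    return [0.4 * (0.1 / 0.4) ** (s / (scales - 1)) for s in range(scales)]


def gabor_bank(scales: int, orientations: int) -> list[np.ndarray]:
    """Complex Gabor kernels, DC-corrected so constant inputs respond zero.

    Frequencies are geometrically spaced in [0.1, 0.4] cycles/pixel (the
    usual texture-retrieval band; lower frequencies would need kernels
    wider than typical working image sizes); orientations are evenly
    spaced over [0, pi).
    """
    kernels = []
    for freq in gabor_frequencies(scales):
        for o in range(orientations):
            theta = np.pi * o / orientations
            k = gabor_kernel(frequency=freq, theta=theta)
            kernels.append(k - k.mean())
    return kernels


def gabor_features(image, scales: int = 4, orientations: int = 6) -> np.ndarray:
    """Mean and std of response magnitude per Gabor kernel.

    Length ``2 * scales * orientations``; ordered scale-major,
    orientation-minor, (mean, std) per kernel.
    """
    px = _as_pixels(image)
    gray = rgb2gray(px)
    feats = []
    for k in gabor_bank(scales, orientations):
        if k.shape[0] > gray.shape[0] or k.shape[1] > gray.shape[1]:
            raise ValueError(
                f"gabor kernel {k.shape} larger than image {gray.shape}"
            )
        # symmetric padding removes boundary truncation, so DC-corrected
        # kernels respond exactly zero on constant images
        py, px_ = k.shape[0] // 2, k.shape[1] // 2
        padded = np.pad(gray, ((py, py), (px_, px_)), mode="symmetric")
        resp = fftconvolve(padded, k, mode="same")
        mag = np.abs(resp[py : py + gray.shape[0], px_ : px_ + gray.shape[1]])
        feats.extend([mag.mean(), mag.std()])
    return np.array(feats)


def compose_f1(
    image,
    config: HandcraftedConfig = HandcraftedConfig(),
    scaler: "HandcraftedScaler | None" = None,
) -> HandcraftedVector:
    """Concatenate [HSV hist | autocorrelogram | color moments | Gabor].

    The raw vector is a pure function of the pixels.  Pass a fitted
    :class:`HandcraftedScaler` to z-score with training-set statistics
    (without it, families on different scales dominate distances
    arbitrarily).
    """
    parts = [
        ("hsv_histogram", hsv_histogram(image, config.hsv_bins)),
        (
            "autocorrelogram",
            color_autocorrelogram(
                image, config.correlogram_distances, config.correlogram_levels
            ),
        ),
        ("color_moments", color_moments(image)),
        ("gabor", gabor_features(image, config.gabor_scales, config.gabor_orientations)),
    ]
    segments = {}
    pos = 0
    chunks = []
    for name, vec in parts:
        segments[name] = (pos, pos + len(vec))
        pos += len(vec)
        chunks.append(vec)
    values = np.concatenate(chunks)
    if scaler is not None:
        values = scaler.transform(values[None, :])[0]
    return HandcraftedVector(values, segments)


def compose_f1_matrix(
    images: list[LabeledImage],
    config: HandcraftedConfig = HandcraftedConfig(),
) -> np.ndarray:
    """Raw (unscaled) f1 vectors of many images, stacked (N, D)."""
    return np.stack([compose_f1(img, config).values for img in images])


class HandcraftedScaler:
    """Per-dimension z-scoring with training-set mean and std.

    Constant dimensions (std 0) are left centered but unscaled.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, matrix: np.ndarray) -> "HandcraftedScaler":
        self.mean_ = matrix.mean(axis=0)
        std = matrix.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler not fitted")
        return (matrix - self.mean_) / self.std_

    def fit_transform(self, matrix: np.ndarray) -> np.ndarray:
        return self.fit(matrix).transform(matrix)


def baseline_score_table(
    train_vectors: np.ndarray,
    train_labels: list[str],
    method: str = "knn",
    params: dict | None = None,
    train_ids: list[str] | None = None,
):
    """Fit KNN or SVM on handcrafted vectors; score training rows.

    Returns ``(table, score_fn)``: ``table`` is the N x C lookup table of
    the training images' class-score vectors (KNN: neighbor class-vote
    fractions; SVM: one-vs-rest decision values) and ``score_fn`` maps a
    (M, D) query matrix into the same C-dimensional score space, so the
    deep retrieval machinery applies unchanged.
    """
    params = dict(params or {})
    train_vectors = np.asarray(train_vectors, dtype=np.float64)
    classes = sorted(set(train_labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a baseline")
    if train_ids is None:
        train_ids = [f"train-{i}" for i in range(len(train_labels))]
    if method == "knn":
        model = KNeighborsClassifier(
            n_neighbors=params.pop("k", 5), metric=params.pop("metric", "euclidean")
        )
        model.fit(train_vectors, train_labels)
        score_fn = model.predict_proba
    elif method == "svm":
        model = SVC(
            kernel=params.pop("kernel", "linear"),
            decision_function_shape="ovr",
            random_state=params.pop("seed", 0),
        )
        model.fit(train_vectors, train_labels)

        def score_fn(X):
            d = model.decision_function(X)
            if d.ndim == 1:  # binary: expand to two ovr columns
                d = np.column_stack([-d, d])
            return d

    else:
        raise ValueError(f"unknown baseline method {method!r}; expected knn or svm")
    class_order = tuple(str(c) for c in model.classes_)
    rows = score_fn(train_vectors)
    table = LookupTable(rows, tuple(train_ids), tuple(train_labels), class_order)
    return table, score_fn
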