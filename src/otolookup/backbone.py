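"""Backbone contract and transfer-learning feature extraction.

The retrieval method is generic: any classification CNN with a global
average-pooling feature layer followed by a fully connected (FC) layer
can be converted into a retrieval system.  This module defines that
contract (:class:`Backbone`) and ships :class:`TinyCNN`, a small NumPy
CNN that trains on a CPU in seconds.

Transfer learning here means the convolutional stages are *frozen*
(their parameters never change) and only the classification head — the
FC layer feeding softmax cross-entropy — is retrained on the target
images.  With frozen features this reduces to seeded mini-batch softmax
regression on the pooled feature vectors, which is exact, fast and
reproducible.  Freeze integrity is checkable via a parameter hash.
"""

from __future__ import annotations

import copy as _copy
import hashlib
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .images import CLASSES, LabeledImage


@dataclass(frozen=True)
class FeatureVector:
    """Pooled feature vector of one image (output of the GAP layer)."""

    values: np.ndarray
    image_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("feature vector must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector has non-finite entries")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ProjectionWeights:
    """FC-layer weights W (F x C), bias b (C,), and the class order."""

    W: np.ndarray
    b: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        if W.ndim != 2 or b.shape != (W.shape[1],):
            raise ValueError(f"inconsistent shapes W{W.shape}, b{b.shape}")
        if len(self.class_order) != W.shape[1]:
            raise ValueError("class_order length must equal the number of columns of W")
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
            raise ValueError("non-finite projection weights")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)

    @property
    def feature_dim(self) -> int:
        return self.W.shape[0]

    @property
    def num_classes(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    """Head-retraining hyperparameters.

    ``retrain_layer_count`` names how many trailing layers are trainable;
    for :class:`TinyCNN` the trainable tail is always the FC layer plus
    its softmax/cross-entropy head (the convolutional stages are frozen
    by construction).
    """

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 0.05
    seed: int = 0
    retrain_layer_count: int = 2

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("batch_size and learning_rate must be positive")


class Backbone:
    """Abstract contract: pooled features plus a final FC layer.

    Implementations expose ``input_size``, ``feature_dim``,
    ``num_classes`` and ``class_order``; compute pooled features from a
    preprocessed raster; and own the FC projection used both for
    classification and for building the retrieval lookup table.
    """

    input_size: tuple[int, int]
    feature_dim: int
    num_classes: int
    class_order: tuple[str, ...]

    def pooled_features(self, pixels: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def projection(self) -> ProjectionWeights:  # pragma: no cover
        raise NotImplementedError

    def set_projection(self, W: np.ndarray, b: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def frozen_parameter_hash(self) -> str:  # pragma: no cover
        raise NotImplementedError

    def copy(self) -> "Backbone":
        return _copy.deepcopy(self)

    # Convenience built on the primitives -------------------------------

    def scores(self, pixels: np.ndarray) -> np.ndarray:
        """Pre-softmax class scores of one image (full forward pass)."""
        pw = self.projection()
        return self.pooled_features(pixels) @ pw.W + pw.b

    def predict_label(self, pixels: np.ndarray) -> str:
        return self.class_order[int(np.argmax(self.scores(pixels)))]


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution: x (H,W,Cin), w (3,3,Cin,Cout) -> (H,W,Cout)."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(0, 1))  # (H, W, Cin, 3, 3)
    return np.einsum("hwcij,ijco->hwo", win, w, optimize=True) + b


def _pool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    return x.reshape(h // 2, 2, w // 2, 2, c).mean(axis=(1, 3))


class TinyCNN(Backbone):
    """Three frozen conv blocks -> global average pool -> FC head.

    The conv filters are fixed at seeded He-initialized random values and
    never trained — they play the role of the frozen pretrained stages of
    a large network, providing a nonlinear color/texture embedding.  Only
    the FC head (``W``: feature_dim x num_classes, ``b``) is trainable.

    Layer list (total 11): conv1, relu1, pool1, conv2, relu2, pool2,
    conv3, relu3, gap, fc, softmax; the first 9 are frozen.
    """

    TOTAL_LAYER_COUNT = 11
    FROZEN_LAYER_COUNT = 9

    def __init__(
        self,
        input_size: tuple[int, int] = (32, 32),
        feature_dim: int = 32,
        class_order: tuple[str, ...] = CLASSES,
        seed: int = 0,
        channels: tuple[int, int] = (16, 32),
    ) -> None:
        if min(input_size) < 4 or input_size[0] % 4 or input_size[1] % 4:
            raise ValueError("input_size must be multiples of 4 (two 2x2 pools)")
        self.input_size = tuple(input_size)
        self.feature_dim = int(feature_dim)
        self.class_order = tuple(class_order)
        self.num_classes = len(self.class_order)
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        self.conv_weights = []
        self.conv_biases = []
        for cin, cout in ((3, c1), (c1, c2), (c2, feature_dim)):
            std = np.sqrt(2.0 / (9 * cin))  # He initialization
            self.conv_weights.append(rng.normal(0.0, std, size=(3, 3, cin, cout)))
            self.conv_biases.append(np.zeros(cout))
        self.W = rng.normal(0.0, 0.01, size=(feature_dim, self.num_classes))
        self.b = np.zeros(self.num_classes)

    # -- preprocessing ---------------------------------------------------

    def prepare_input(self, pixels: np.ndarray) -> np.ndarray:
        """Resize (bilinear) to ``input_size`` and scale to [-1, 1]."""
        px = np.asarray(pixels, dtype=np.float64)
        if px.size == 0:
            raise ValueError("empty image")
        if px.shape[:2] != self.input_size:
            px = resize(px, self.input_size, order=1, preserve_range=True, anti_aliasing=False)
        return px / 127.5 - 1.0

    # -- forward ----------------------------------------------------------

    def pooled_features(self, pixels: np.ndarray) -> np.ndarray:
        x = self.prepare_input(pixels)
        x = np.maximum(_conv_same(x, self.conv_weights[0], self.conv_biases[0]), 0.0)
        x = _pool2(x)
        x = np.maximum(_conv_same(x, self.conv_weights[1], self.conv_biases[1]), 0.0)
        x = _pool2(x)
        x = np.maximum(_conv_same(x, self.conv_weights[2], self.conv_biases[2]), 0.0)
        return x.mean(axis=(0, 1))  # global average pool

    # -- projection / freeze ----------------------------------------------

    def projection(self) -> ProjectionWeights:
        return ProjectionWeights(self.W.copy(), self.b.copy(), self.class_order)

    def set_projection(self, W: np.ndarray, b: np.ndarray) -> None:
        W = np.asarray(W, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if W.shape != (self.feature_dim, self.num_classes) or b.shape != (self.num_classes,):
            raise ValueError("projection shape mismatch")
        self.W, self.b = W.copy(), b.copy()

    def frozen_parameter_hash(self) -> str:
        h = hashlib.sha256()
        for w, b in zip(self.conv_weights, self.conv_biases):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            input_size=np.array(self.input_size),
            feature_dim=self.feature_dim,
            seed=self.seed,
            class_order=np.array(self.class_order),
            channels=np.array([w.shape[3] for w in self.conv_weights[:2]]),
            W=self.W,
            b=self.b,
            **{f"conv_w{i}": w for i, w in enumerate(self.conv_weights)},
            **{f"conv_b{i}": b for i, b in enumerate(self.conv_biases)},
        )

    @classmethod
    def load(cls, path) -> "TinyCNN":
        data = np.load(path, allow_pickle=False)
        model = cls(
            input_size=tuple(int(v) for v in data["input_size"]),
            feature_dim=int(data["feature_dim"]),
            class_order=tuple(str(c) for c in data["class_order"]),
            seed=int(data["seed"]),
            channels=tuple(int(v) for v in data["channels"]),
        )
        model.conv_weights = [data[f"conv_w{i}"] for i in range(3)]
        model.conv_biases = [data[f"conv_b{i}"] for i in range(3)]
        model.W = data["W"]
        model.b = data["b"]
        return model


# -- module-level operations -----------------------------------------------


def extract_features(backbone: Backbone, image: LabeledImage) -> FeatureVector:
    """Pooled feature vector of one image (deterministic, inference mode)."""
    return FeatureVector(backbone.pooled_features(image.pixels), image.id)


def extract_feature_matrix(
    backbone: Backbone, images: list[LabeledImage]
) -> tuple[np.ndarray, list[str]]:
    """Stack pooled features of many images into an (N, F) matrix."""
    feats = np.stack([backbone.pooled_features(img.pixels) for img in images])
    return feats, [img.id for img in images]


def get_projection(backbone: Backbone) -> ProjectionWeights:
    """The backbone's FC weights, oriented feature_dim x num_classes."""
    return backbone.projection()


@dataclass
class FineTuneResult:
    backbone: Backbone
    val_accuracy: list[float] = field(default_factory=list)

    def __iter__(self):  # allow `model, history = fine_tune(...)`
        return iter((self.backbone, self.val_accuracy))


def _labels_to_indices(images: list[LabeledImage], class_order) -> np.ndarray:
    idx = {c: i for i, c in enumerate(class_order)}
    try:
        return np.array([idx[img.label] for img in images])
    except KeyError as e:  # pragma: no cover - message clarity
        raise ValueError(f"label {e} not in backbone class order {class_order}") from e


def fit_head(
    backbone: Backbone,
    train_features: np.ndarray,
    train_targets: np.ndarray,
    val_features: np.ndarray,
    val_targets: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Train the FC softmax head in place on precomputed pooled features.

    Seeded mini-batch SGD with momentum 0.9 on softmax cross-entropy.
    Returns the per-epoch validation classification accuracy.
    """
    rng = np.random.default_rng(cfg.seed)
    pw = backbone.projection()
    W, b = pw.W, pw.b
    n = train_features.shape[0]
    onehot = np.eye(backbone.num_classes)[train_targets]
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            X, Y = train_features[sel], onehot[sel]
            logits = X @ W + b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            g = (p - Y) / len(sel)
            gW = X.T @ g
            gb = g.sum(axis=0)
            vW = 0.9 * vW - cfg.learning_rate * gW
            vb = 0.9 * vb - cfg.learning_rate * gb
            W = W + vW
            b = b + vb
        val_pred = np.argmax(val_features @ W + b, axis=1)
        history.append(float(np.mean(val_pred == val_targets)))
    backbone.set_projection(W, b)
    return history


def fine_tune(
    backbone: Backbone,
    train: list[LabeledImage],
    val: list[LabeledImage],
    cfg: TrainConfig,
) -> FineTuneResult:
    """Retrain the FC head on ``train``, tracking accuracy on ``val``.

    The input backbone is left untouched; a copy is returned.  The frozen
    convolutional parameters of the copy are bit-identical to the input
    (verifiable via :meth:`Backbone.frozen_parameter_hash`); with
    ``epochs=0`` the copy is identical everywhere.
    """
    if not train or not val:
        raise ValueError("train and val must both be non-empty")
    model = backbone.copy()
    y_tr = _labels_to_indices(train, model.class_order)
    y_va = _labels_to_indices(val, model.class_order)
    if cfg.epochs == 0:
        return FineTuneResult(model, [])
    X_tr, _ = extract_feature_matrix(model, train)
    X_va, _ = extract_feature_matrix(model, val)
    history = fit_head(model, X_tr, y_tr, X_va, y_va, cfg)
    return FineTuneResult(model, history)
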