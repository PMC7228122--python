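"""Class-score lookup table and nearest-neighbor retrieval.

The conversion from classifier to retrieval system: each database
image's pooled feature vector f (length F) is projected through the FC
weights W (F x C) into a C-dimensional class-score vector fᵀW (+ b).
Stacking these rows gives the N x C *lookup table*.  A query image is
projected the same way and the nearest rows under Chebyshev (L∞) or
cosine distance are returned as the most similar images.

Lookup vectors are raw pre-softmax class scores; optional L2
normalization of rows and queries is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import FeatureVector, ProjectionWeights

METRICS = ("chebyshev", "cosine")


@dataclass(frozen=True)
class LookupTable:
    """N x C matrix of class-score rows with aligned ids and labels."""

    rows: np.ndarray
    ids: tuple[str, ...]
    labels: tuple[str, ...]
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.ndim != 2 or rows.shape[0] < 1:
            raise ValueError("lookup table must be a non-empty 2-D matrix")
        if rows.shape[1] != len(self.class_order):
            raise ValueError("row length must equal the number of classes")
        if len(self.ids) != rows.shape[0] or len(self.labels) != rows.shape[0]:
            raise ValueError("ids/labels must align with rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in lookup table")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return self.rows.shape[0]


@dataclass(frozen=True)
class RetrievedItem:
    id: str
    label: str
    distance: float


@dataclass(frozen=True)
class QueryResult:
    """Ranked retrieval list for one query under one metric and one k."""

    query_id: str
    metric: str
    k: int
    items: tuple[RetrievedItem, ...]

    def __post_init__(self) -> None:
        d = [it.distance for it in self.items]
        if any(b < a - 1e-12 for a, b in zip(d, d[1:])):
            raise ValueError("distances must be non-decreasing down the ranking")
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]


def project(
    feature: FeatureVector | np.ndarray,
    pw: ProjectionWeights,
    use_bias: bool = True,
) -> np.ndarray:
    """Project a pooled feature vector into class-score space: fᵀW (+ b)."""
    f = feature.values if isinstance(feature, FeatureVector) else np.asarray(feature, float)
    if f.shape != (pw.feature_dim,):
        raise ValueError(f"feature length {f.shape} != expected ({pw.feature_dim},)")
    out = f @ pw.W
    if use_bias:
        out = out + pw.b
    return out


def build_lookup(
    features: list[FeatureVector],
    labels: list[str],
    pw: ProjectionWeights,
    use_bias: bool = True,
    normalize: bool = False,
) -> LookupTable:
    """Project every database feature into a row of the lookup table.

    Row i is ``project(features[i])``; ids and labels keep input order.
    ``normalize=True`` L2-normalizes rows (off by default: raw scores).
    """
    if not features:
        raise ValueError("cannot build a lookup table from zero features")
    if len(labels) != len(features):
        raise ValueError("labels must align with features")
    rows = np.stack([project(f, pw, use_bias) for f in features])
    if normalize:
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot L2-normalize a zero row")
        rows = rows / norms
    return LookupTable(rows, tuple(f.image_id for f in features), tuple(labels), pw.class_order)


def chebyshev_distance(x: np.ndarray, y: np.ndarray) -> float:
    """L∞ distance: max over coordinates of |x_j - y_j|."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.max(np.abs(x - y)))


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cos(angle between x and y); in [0, 2]; undefined for zero vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("undefined cosine: zero-norm vector")
    return float(1.0 - float(x @ y) / (nx * ny))


def _distances_to_rows(query: np.ndarray, rows: np.ndarray, metric: str) -> np.ndarray:
    if metric == "chebyshev":
        return np.max(np.abs(rows - query), axis=1)
    if metric == "cosine":
        qn = np.linalg.norm(query)
        rn = np.linalg.norm(rows, axis=1)
        if qn == 0.0:
            raise ValueError("undefined cosine: zero-norm query")
        if np.any(rn == 0.0):
            raise ValueError("undefined cosine: zero-norm lookup row")
        return 1.0 - (rows @ query) / (rn * qn)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def retrieve(
    query: np.ndarray,
    table: LookupTable,
    k: int,
    metric: str = "cosine",
    query_id: str = "query",
    normalize: bool = False,
) -> QueryResult:
    """Top-``min(k, N)`` nearest lookup rows to a projected query vector.

    Rows are sorted by ascending distance; ties break deterministically
    by insertion index (stable sort).  ``normalize=True`` L2-normalizes
    the query to match a normalized table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = np.asarray(query, dtype=np.float64)
    if q.shape != (table.rows.shape[1],):
        raise ValueError("query length must equal the table row length")
    if normalize:
        qn = np.linalg.norm(q)
        if qn == 0.0:
            raise ValueError("cannot L2-normalize a zero query")
        q = q / qn
    dist = _distances_to_rows(q, table.rows, metric)
    order = np.argsort(dist, kind="stable")[: min(k, len(table))]
    items = tuple(
        RetrievedItem(table.ids[i], table.labels[i], float(dist[i])) for i in order
    )
    return QueryResult(query_id, metric, k, items)


# -- serialization -----------------------------------------------------------


def save_lookup(table: LookupTable, path: str | Path) -> None:
    """Write a lookup table as CSV: id, label, score_<class>..."""
    df = pd.DataFrame({"id": table.ids, "label": table.labels})
    for j, cls in enumerate(table.class_order):
        df[f"score_{cls}"] = table.rows[:, j]
    pd.DataFrame(df).to_csv(path, index=False)


def load_lookup(path: str | Path) -> LookupTable:
    df = pd.read_csv(path, dtype={"id": str, "label": str})
    score_cols = [c for c in df.columns if c.startswith("score_")]
    class_order = tuple(c[len("score_") :] for c in score_cols)
    return LookupTable(
        df[score_cols].to_numpy(dtype=np.float64),
        tuple(df["id"]),
        tuple(df["label"]),
        class_order,
    )
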