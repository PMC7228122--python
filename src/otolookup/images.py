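"""Core image container and manifest I/O.

Every stage of the pipeline consumes and produces :class:`LabeledImage`
objects: an 8-bit RGB raster plus a diagnostic class label and a stable
string identifier.  Datasets on disk are a directory of PNG/JPEG files
described by a manifest CSV with columns ``id, path, label, split``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: The three diagnostic categories, in canonical order.
CLASSES: tuple[str, ...] = ("effusion", "normal", "tube")

MANIFEST_COLUMNS = ["id", "path", "label", "split"]


@dataclass
class LabeledImage:
    """An 8-bit RGB image with a class label and a unique identifier.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (height, width, 3)
        The raster.  Pipeline input images are expected to be at least
        8x8 (the generator and loaders guarantee this); the container
        itself also holds smaller intermediate crops.
    label : str
        One of :data:`CLASSES`.
    id : str
        Stable unique identifier within a dataset.
    """

    pixels: np.ndarray
    label: str
    id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image raster")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASSES}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "LabeledImage":
        """Copy of this image with new pixels, same label and id."""
        return replace(self, pixels=pixels)


def write_dataset(
    images: list[LabeledImage],
    out_dir: str | Path,
    splits: dict[str, str] | None = None,
) -> Path:
    """Write images as PNG files plus a ``manifest.csv``.

    Returns the manifest path. ``splits`` optionally maps image id to a
    split name (train/validation/test); unknown ids get an empty split.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        fname = f"{img.id}.png"
        iio.imwrite(out_dir / fname, img.pixels)
        split = (splits or {}).get(img.id, "")
        rows.append({"id": img.id, "path": fname, "label": img.label, "split": split})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV, validating its columns."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns: {missing}")
    if df["id"].duplicated().any():
        raise ValueError("manifest has duplicate ids")
    return df


def load_dataset(manifest_path: str | Path) -> list[LabeledImage]:
    """Load all images referenced by a manifest CSV.

    Relative image paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    images = []
    for row in df.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = root / path
        px = np.asarray(iio.imread(path))
        if px.ndim == 2:  # grayscale file: promote to RGB
            px = np.stack([px] * 3, axis=-1)
        if px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        images.append(LabeledImage(pixels=px.astype(np.uint8), label=row.label, id=row.id))
    return images
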