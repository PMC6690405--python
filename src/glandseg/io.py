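"""Raster and manifest I/O.

Images are 8-bit RGB tiles (PNG/TIFF/BMP); instance masks are single-channel
integer rasters stored as 16-bit PNG/TIFF.  Binary masks are written as 8-bit
PNG with values {0, 255}.  Lossy formats are refused for masks, since a single
recompressed label pixel silently corrupts the ground truth.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DataError, FormatError

log = logging.getLogger("glandseg")

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}
_MASK_SUFFIXES = {".png", ".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB tissue tile as a (H, W, 3) uint8 array.

    4-channel input with an alpha channel is accepted; the alpha channel is
    dropped with a logged warning.  Grayscale input is refused.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format {path.suffix!r}: {path}")
    with Image.open(path) as im:
        if im.mode == "RGBA":
            log.warning("dropping alpha channel of %s", path)
            im = im.convert("RGB")
        if im.mode != "RGB":
            raise FormatError(
                f"expected a 3-channel RGB image, got mode {im.mode!r}: {path}"
            )
        arr = np.asarray(im, dtype=np.uint8)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a (H, W, 3) uint8 array as an RGB raster (format from suffix)."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) array, got shape {image.shape}")
    Image.fromarray(image.astype(np.uint8), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an integer instance mask as a (H, W) array of non-negative ints.

    Accepts 8- or 16-bit single-channel PNG/TIFF.  JPEG (or any other lossy
    format) raises a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mask file not found: {path}")
    if path.suffix.lower() not in _MASK_SUFFIXES:
        raise FormatError(
            f"masks must be lossless PNG/TIFF, got {path.suffix!r}: {path}"
        )
    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I"):
            arr = np.asarray(im, dtype=np.int64)
        elif im.mode == "L":
            arr = np.asarray(im, dtype=np.int64)
        else:
            raise FormatError(
                f"expected a single-channel integer mask, got mode {im.mode!r}: {path}"
            )
    if arr.min() < 0:
        raise FormatError(f"mask contains negative labels: {path}")
    return arr


def write_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer instance mask as 16-bit single-channel PNG/TIFF."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise FormatError(f"expected a 2-D label raster, got shape {labels.shape}")
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise FormatError("labels must fit in uint16")
    im = Image.fromarray(labels.astype(np.int32), mode="I").convert("I;16")
    im.save(path)


def write_binary_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG with values {0, 255}."""
    mask = np.asarray(mask).astype(bool)
    Image.fromarray((mask * np.uint8(255)), mode="L").save(Path(path))


def read_binary_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit (or 16-bit) mask and binarize: any nonzero pixel is 1."""
    return (read_mask(path) > 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["image", "annotation", "split", "morphology"]


def load_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load a dataset manifest CSV (columns image, annotation, split, morphology).

    Paths are resolved relative to the manifest's own directory.  Image ids
    (file stems) must be unique and, when ``check_files``, every referenced
    file must exist.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing_cols = [c for c in ("image", "annotation") if c not in df.columns]
    if missing_cols:
        raise DataError(f"manifest {path} lacks columns {missing_cols}")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    base = path.parent
    df["image"] = [str((base / p).resolve()) if not Path(p).is_absolute() else p
                   for p in df["image"]]
    df["annotation"] = [str((base / p).resolve()) if not Path(p).is_absolute() else p
                        for p in df["annotation"]]
    if df.empty:
        raise DataError(f"manifest {path} is empty")
    ids = [Path(p).stem for p in df["image"]]
    if len(set(ids)) != len(ids):
        raise DataError(f"manifest {path} has duplicate image ids")
    if check_files:
        missing = [p for p in list(df["image"]) + list(df["annotation"])
                   if p and not Path(p).exists()]
        if missing:
            raise DataError(f"manifest references missing files: {missing[:5]}")
    return df[MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]]


def save_manifest(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), index=False)
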