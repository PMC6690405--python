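"""Supervision targets derived from gland instance annotations.

The dual-decoder network needs two ground truths per tile and per approach:

* gland approach   — binarized gland mask + gland-contour mask;
* stroma approach  — stroma mask (white pixels thresholded away, intersected
  with the inverted gland annotation) + stroma-contour mask.

Conventions used throughout the package: rasters are row-major, 0-based,
boundaries use 4-connectivity (a boundary pixel has a 4-neighbour with a
different label, where outside the frame counts as background), connected
components use 8-connectivity, and a contour of thickness ``t`` is the set
of boundary pixels dilated ``t - 1`` times with a 3×3 cross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, ShapeError

#: 3×3 cross structuring element (4-connectivity).
CROSS = ndimage.generate_binary_structure(2, 1)

#: Gray level above which a pixel counts as white (lumen / background).
DEFAULT_WHITE_THRESHOLD = 220.0

#: Contour band thickness (pixels) at the 480×480 training resolution.
DEFAULT_CONTOUR_THICKNESS = 2

#: ITU-R 601 luma weights for RGB → gray.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class TargetPair:
    """Binary object mask + binary contour mask for one approach."""

    object_mask: np.ndarray
    contour_mask: np.ndarray
    approach: str  # "gland" | "stroma"


@dataclass(frozen=True)
class TissuePartition:
    """Disjoint gland/stroma/white rasters covering every pixel."""

    gland: np.ndarray
    stroma: np.ndarray
    white: np.ndarray


def to_gray(tile: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an RGB tile, as float64 in [0, 255]."""
    return np.asarray(tile, dtype=np.float64) @ _LUMA


def binarize_gland_mask(inst: np.ndarray) -> np.ndarray:
    """Binary gland mask: 1 wherever the instance label is positive."""
    return (np.asarray(inst) > 0).astype(np.uint8)


def _boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Labelled pixels that 4-touch a pixel of a different label or the frame."""
    labels = np.asarray(labels)
    padded = np.pad(labels, 1, mode="constant", constant_values=0)
    center = padded[1:-1, 1:-1]
    boundary = np.zeros(labels.shape, dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr:padded.shape[0] - 1 + dr,
                       1 + dc:padded.shape[1] - 1 + dc]
        boundary |= (center != neigh)
    return boundary & (labels > 0)


def extract_contour_mask(inst: np.ndarray, thickness: int = DEFAULT_CONTOUR_THICKNESS
                         ) -> np.ndarray:
    """Binary contour band of every instance boundary.

    Touching instances both contribute contour pixels, so subtracting the
    contour from the object mask separates adjacent glands.
    """
    if thickness < 1:
        raise InvalidParameterError("contour thickness must be >= 1")
    boundary = _boundary_pixels(inst)
    if thickness > 1:
        boundary = ndimage.binary_dilation(boundary, CROSS, iterations=thickness - 1)
    return boundary.astype(np.uint8)


def gland_targets(inst: np.ndarray, thickness: int = DEFAULT_CONTOUR_THICKNESS
                  ) -> TargetPair:
    """Gland-approach supervision: binarized gland mask + contour mask."""
    return TargetPair(
        object_mask=binarize_gland_mask(inst),
        contour_mask=extract_contour_mask(inst, thickness),
        approach="gland",
    )


def derive_stroma_mask(tile: np.ndarray, inst: np.ndarray,
                       white_threshold: float = DEFAULT_WHITE_THRESHOLD
                       ) -> TissuePartition:
    """Three-way tissue partition: gland, white, stroma.

    White pixels are thresholded on the gray-scale tile; the stroma is the
    pixel-wise intersection of the inverted gland annotation with the
    non-white pixels.  Precedence gland > white > stroma forces an exact
    disjoint partition.
    """
    tile = np.asarray(tile)
    inst = np.asarray(inst)
    if tile.shape[:2] != inst.shape:
        raise ShapeError(f"tile {tile.shape[:2]} and mask {inst.shape} differ")
    if not (0 < white_threshold < 255):
        raise InvalidParameterError("white_threshold must lie in (0, 255)")
    gland = inst > 0
    white = (to_gray(tile) > white_threshold) & ~gland
    stroma = ~gland & ~white
    return TissuePartition(gland=gland.astype(np.uint8),
                           stroma=stroma.astype(np.uint8),
                           white=white.astype(np.uint8))


def stroma_targets(partition: TissuePartition,
                   thickness: int = DEFAULT_CONTOUR_THICKNESS) -> TargetPair:
    """Stroma-approach supervision: stroma mask + stroma-contour band."""
    stroma = np.asarray(partition.stroma).astype(np.uint8)
    contour = extract_contour_mask(stroma, thickness)
    return TargetPair(object_mask=stroma, contour_mask=contour, approach="stroma")


def targets_for_approach(tile: np.ndarray, inst: np.ndarray, approach: str,
                         thickness: int = DEFAULT_CONTOUR_THICKNESS,
                         white_threshold: float = DEFAULT_WHITE_THRESHOLD
                         ) -> TargetPair:
    """Dispatch to gland or stroma supervision targets."""
    if approach == "gland":
        return gland_targets(inst, thickness)
    if approach == "stroma":
        return stroma_targets(derive_stroma_mask(tile, inst, white_threshold),
                              thickness)
    raise InvalidParameterError(f"unknown approach {approach!r}")
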