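"""Segmentation evaluation: Dice coefficient and Hausdorff distance.

Dice measures volume overlap between the ground-truth pixel set G and the
segmented pixel set S,

    Dice(G, S) = 2 |G ∩ S| / (|G| + |S|),

ranging from 0 (disjoint) to 1 (identical).  The Hausdorff distance measures
the worst-case boundary disagreement: the directed distance is
sup_{y in S} inf_{x in G} d(x, y) over boundary pixels with Euclidean d; the
symmetric distance is the max of the two directions and is the default.
Hausdorff is computed on boundary pixels via an exact Euclidean distance
transform (equivalent to the all-pairs definition, see the test suite).

Evaluation is semantic (whole-tile binary masks).  When both masks are
empty, Dice is reported as 1.0 with an ``empty`` flag and Hausdorff is
skipped with the same flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io
from .errors import PairingError, ShapeError, UndefinedMetricError


@dataclass
class EvalResult:
    """Per-image Dice/Hausdorff rows plus dataset aggregates."""

    per_image: pd.DataFrame
    mean_dice: float
    mean_hausdorff: float
    hausdorff_mode: str = "symmetric"
    resolution: str = ""
    flags: dict[str, str] = field(default_factory=dict)


def _as_binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask) > 0


def dice_coefficient(G: np.ndarray, S: np.ndarray) -> float:
    """2|G∩S| / (|G|+|S|); symmetric; 1.0 (by convention) when both empty."""
    G, S = _as_binary(G), _as_binary(S)
    if G.shape != S.shape:
        raise ShapeError(f"mask shapes differ: {G.shape} vs {S.shape}")
    denom = int(G.sum()) + int(S.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((G & S).sum()) / denom


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boundary of a binary mask: set pixels 4-adjacent to background/frame."""
    mask = _as_binary(mask)
    eroded = ndimage.binary_erosion(
        mask, ndimage.generate_binary_structure(2, 1), border_value=0)
    return mask & ~eroded


def _directed_hausdorff(from_boundary: np.ndarray, to_boundary: np.ndarray) -> float:
    """sup over `from` boundary pixels of distance to nearest `to` boundary pixel."""
    dist_to = ndimage.distance_transform_edt(~to_boundary)
    return float(dist_to[from_boundary].max())


def hausdorff_distance(G: np.ndarray, S: np.ndarray, mode: str = "symmetric"
                       ) -> float:
    """Hausdorff distance in pixels between the boundaries of G and S.

    ``mode='symmetric'`` (default) is max(h(G→S), h(S→G)); ``mode='directed'``
    is the one-sided h(S→G).  Raises for empty masks.
    """
    if mode not in ("symmetric", "directed"):
        raise ValueError(f"unknown hausdorff mode {mode!r}")
    G, S = _as_binary(G), _as_binary(S)
    if G.shape != S.shape:
        raise ShapeError(f"mask shapes differ: {G.shape} vs {S.shape}")
    if not G.any() or not S.any():
        raise UndefinedMetricError("hausdorff distance undefined for an empty mask")
    bG, bS = boundary_pixels(G), boundary_pixels(S)
    s_to_g = _directed_hausdorff(bS, bG)
    if mode == "directed":
        return s_to_g
    g_to_s = _directed_hausdorff(bG, bS)
    return max(s_to_g, g_to_s)


def evaluate_pairs(pairs: list[tuple[str, np.ndarray, np.ndarray]],
                   hausdorff_mode: str = "symmetric",
                   resolution: str = "") -> EvalResult:
    """Evaluate a list of (id, truth, prediction) binary mask pairs."""
    rows = []
    flags: dict[str, str] = {}
    for image_id, truth, pred in pairs:
        d = dice_coefficient(truth, pred)
        t_any, p_any = bool(np.any(truth)), bool(np.any(pred))
        if t_any and p_any:
            h = hausdorff_distance(truth, pred, mode=hausdorff_mode)
        else:
            h = np.nan
            flags[image_id] = "empty" if not (t_any or p_any) else "one-sided-empty"
        rows.append({"image_id": image_id, "dice": d, "hausdorff_px": h})
    df = pd.DataFrame(rows)
    return EvalResult(
        per_image=df,
        mean_dice=float(df["dice"].mean()),
        mean_hausdorff=float(df["hausdorff_px"].mean(skipna=True)),
        hausdorff_mode=hausdorff_mode,
        resolution=resolution,
        flags=flags,
    )


def evaluate_dataset(pred_dir: str | Path, truth_dir: str | Path,
                     out_csv: str | Path | None = None,
                     hausdorff_mode: str = "symmetric") -> EvalResult:
    """Pair masks by file stem across two directories and evaluate.

    Unmatched identifiers raise a pairing error listing the orphans.  The CSV
    report records one row per image plus the Hausdorff mode and resolution.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    preds = {p.stem: p for p in sorted(pred_dir.iterdir())
             if p.suffix.lower() in (".png", ".tif", ".tiff")}
    truths = {p.stem: p for p in sorted(truth_dir.iterdir())
              if p.suffix.lower() in (".png", ".tif", ".tiff")}
    orphans = sorted(set(preds) ^ set(truths))
    if orphans:
        raise PairingError(f"unpaired mask identifiers: {orphans}", orphans=orphans)
    if not preds:
        raise PairingError("no mask files found", orphans=[])
    pairs = []
    resolution = ""
    for stem in sorted(preds):
        truth = io.read_mask(truths[stem]) > 0
        pred = io.read_mask(preds[stem]) > 0
        resolution = f"{truth.shape[1]}x{truth.shape[0]}"
        pairs.append((stem, truth, pred))
    result = evaluate_pairs(pairs, hausdorff_mode=hausdorff_mode,
                            resolution=resolution)
    if out_csv is not None:
        df = result.per_image.copy()
        df["hausdorff_mode"] = result.hausdorff_mode
        df["resolution"] = result.resolution
        df.to_csv(Path(out_csv), index=False)
    return result
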