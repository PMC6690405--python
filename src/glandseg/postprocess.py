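"""From probability maps to a final labeled gland mask.

Gland approach: threshold the object and contour maps, dilate the binary
contour twice (3×3 cross), multiply it into the binary gland mask to
separate touching glands, label the result, and re-dilate each labeled
object by the same amount (nearest-seed assignment) to recover the boundary
pixels the contour removed.

Stroma approach: threshold the stroma map, invert it (the inversion marks
gland candidates), exclude white background pixels on the tile, and process
with the stroma-contour map in the same way; white lumina removed along
with the background reappear during hole filling.

Both paths then drop small components, fill holes, and finish with
mean-field inference over a fully connected CRF whose Gaussian appearance
and smoothness kernels sharpen the prediction against the underlying tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, ShapeError
from .masks import CROSS, DEFAULT_WHITE_THRESHOLD, to_gray
from .model import ProbabilityMaps


@dataclass(frozen=True)
class PostprocessConfig:
    t_object: float = 0.5
    t_contour: float = 0.5
    dilation_iters: int = 2
    min_area: int = 200          # pixels, at the 480×480 working resolution
    crf_iters: int = 5
    crf_appearance_sxy: float = 20.0
    crf_appearance_srgb: float = 13.0
    crf_appearance_weight: float = 10.0
    crf_smoothness_sxy: float = 3.0
    crf_smoothness_weight: float = 3.0
    apply_crf: bool = True

    def __post_init__(self):
        if not (0 < self.t_object < 1 and 0 < self.t_contour < 1):
            raise InvalidParameterError("thresholds must lie in (0, 1)")
        if self.min_area < 0 or self.dilation_iters < 0:
            raise InvalidParameterError("min_area and dilation_iters must be >= 0")


_LABEL_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-connectivity for components


def _recover_removed_pixels(labels: np.ndarray, removed: np.ndarray,
                            iters: int) -> np.ndarray:
    """Re-dilate the separated objects over the boundary band the dilated
    contour removed: every ``removed`` object pixel is reassigned to its
    nearest seed (taxicab distance, capped), resolving collisions between
    adjacent glands by proximity.  Pixels outside the thresholded object
    mask are never claimed, so a zero contour map leaves the labeling equal
    to the object map's connected components."""
    if labels.max() == 0 or not removed.any():
        return labels
    dist, (ir, ic) = ndimage.distance_transform_cdt(
        labels == 0, metric="taxicab", return_indices=True)
    out = labels[ir, ic]
    out[~(removed & (dist <= 3 * (iters + 1)))] = 0
    out[labels > 0] = labels[labels > 0]
    return out


def fuse_gland_contour(maps: ProbabilityMaps,
                       cfg: PostprocessConfig = PostprocessConfig()
                       ) -> np.ndarray:
    """Contour-fusion instance extraction from gland + contour maps."""
    gland_bin = np.asarray(maps.object_prob) >= cfg.t_object
    contour_bin = np.asarray(maps.contour_prob) >= cfg.t_contour
    if contour_bin.any() and cfg.dilation_iters:
        contour_bin = ndimage.binary_dilation(contour_bin, CROSS,
                                              iterations=cfg.dilation_iters)
    separated = gland_bin & ~contour_bin
    labels, _ = ndimage.label(separated, structure=_LABEL_STRUCTURE)
    removed = gland_bin & ~separated
    return _recover_removed_pixels(labels, removed,
                                   cfg.dilation_iters).astype(np.int64)


def gland_from_stroma(maps: ProbabilityMaps,
                      cfg: PostprocessConfig = PostprocessConfig(),
                      tile: np.ndarray | None = None,
                      white_threshold: float = DEFAULT_WHITE_THRESHOLD
                      ) -> np.ndarray:
    """Gland instances by stroma inversion.

    The inverted binary stroma mask marks gland candidates; when the tile is
    given, white background pixels (gray above the threshold) are excluded —
    white lumina inside glands are restored later by hole filling in
    :func:`clean_mask`.  The stroma-contour map separates touching glands
    exactly as in the gland path.
    """
    stroma_bin = np.asarray(maps.object_prob) >= cfg.t_object
    candidates = ~stroma_bin
    if tile is not None:
        if tile.shape[:2] != candidates.shape:
            raise ShapeError("tile and probability map shapes differ")
        candidates &= to_gray(tile) <= white_threshold
    inverted_maps = ProbabilityMaps(object_prob=candidates.astype(np.float64),
                                    contour_prob=np.asarray(maps.contour_prob))
    return fuse_gland_contour(inverted_maps, cfg)


def clean_mask(inst: np.ndarray,
               cfg: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Drop components below ``min_area``, fill enclosed holes, relabel 1..n.

    Holes are filled on the union of the surviving objects and each filled
    pixel takes the label of its nearest object, so a lumen enclosed by
    several fragments of one gland ring still fills completely.
    """
    inst = np.asarray(inst)
    out = inst.astype(np.int64).copy()
    if out.max() > 0:
        # area filtering acts on connected components of the binary mask, so
        # a gland carrying several instance labels is kept or dropped whole
        union_cc, n_cc = ndimage.label(out > 0, structure=_LABEL_STRUCTURE)
        if n_cc:
            areas = np.bincount(union_cc.ravel())
            areas[0] = cfg.min_area  # background is never dropped
            out[areas[union_cc] < cfg.min_area] = 0
    if out.max() > 0:
        holes = ndimage.binary_fill_holes(out > 0) & (out == 0)
        if holes.any():
            _, (ir, ic) = ndimage.distance_transform_edt(out == 0,
                                                         return_indices=True)
            out[holes] = out[ir, ic][holes]
    labels = np.unique(out)
    labels = labels[labels > 0]
    remap = np.zeros(int(out.max()) + 1, dtype=np.int64)
    remap[labels] = np.arange(1, labels.size + 1)
    return remap[out]


def crf_refine(tile: np.ndarray, prob: np.ndarray,
               cfg: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Mean-field inference over a fully connected binary CRF.

    Unary potentials are the negative log of {prob, 1−prob}; the pairwise
    term combines an appearance kernel (Gaussian in position and tile color,
    evaluated with a splat–blur–slice bilateral grid) and a smoothness
    kernel (Gaussian in position), both with Potts compatibility.  Returns
    the refined foreground probability.
    """
    tile = np.asarray(tile)
    prob = np.asarray(prob, dtype=np.float64)
    if tile.shape[:2] != prob.shape:
        raise ShapeError("tile and probability map shapes differ")
    p = np.clip(prob, 1e-6, 1 - 1e-6)
    unary = -np.log(np.stack([1 - p, p]))  # (2, H, W): background, foreground
    q = np.stack([1 - p, p])
    grid = _BilateralGrid(tile, cfg.crf_appearance_sxy, cfg.crf_appearance_srgb)
    for _ in range(cfg.crf_iters):
        message = np.empty_like(q)
        for lbl in range(2):
            app = grid.filter(q[lbl])
            smooth = ndimage.gaussian_filter(q[lbl], cfg.crf_smoothness_sxy)
            message[lbl] = (cfg.crf_appearance_weight * app
                            + cfg.crf_smoothness_weight * smooth)
        # Potts compatibility: each label is penalized by the other's mass
        energy = unary + message[::-1]
        energy -= energy.min(axis=0)
        q = np.exp(-energy)
        q /= q.sum(axis=0)
    return q[1]


class _BilateralGrid:
    """Approximate high-dimensional Gaussian (bilateral) filtering by
    splatting onto a coarse (y, x, r, g, b) grid, blurring, and slicing."""

    def __init__(self, tile: np.ndarray, sigma_xy: float, sigma_rgb: float):
        h, w = tile.shape[:2]
        ys, xs = np.mgrid[0:h, 0:w]
        coords = [ys / sigma_xy, xs / sigma_xy]
        for ch in range(3):
            coords.append(tile[..., ch].astype(np.float64) / sigma_rgb)
        self.idx = []
        self.shape = []
        for c in coords:
            i = np.rint(c - c.min()).astype(np.intp)
            self.idx.append(i.ravel())
            self.shape.append(int(i.max()) + 1)
        self.flat = np.ravel_multi_index(self.idx, self.shape)
        self.size = int(np.prod(self.shape))
        self.out_shape = (h, w)
        weight = np.bincount(self.flat, minlength=self.size).astype(np.float64)
        weight = ndimage.gaussian_filter(
            weight.reshape(self.shape), sigma=1.0, truncate=2.0).ravel()
        self.norm = np.maximum(weight, 1e-12)

    def filter(self, values: np.ndarray) -> np.ndarray:
        grid = np.bincount(self.flat, weights=values.ravel(),
                           minlength=self.size).astype(np.float64)
        grid = ndimage.gaussian_filter(grid.reshape(self.shape), sigma=1.0,
                                       truncate=2.0).ravel()
        return (grid / self.norm)[self.flat].reshape(self.out_shape)


def segment(maps: ProbabilityMaps, approach: str,
            tile: np.ndarray | None = None,
            cfg: PostprocessConfig = PostprocessConfig(),
            white_threshold: float = DEFAULT_WHITE_THRESHOLD) -> np.ndarray:
    """Full post-processing chain for one tile → labeled instance mask.

    Contour fusion (or stroma inversion), component cleaning, then — when a
    tile is available — CRF refinement of the binary mask with final
    binarization at 0.5; instance labels are carried through the CRF by
    nearest-seed assignment.
    """
    if approach == "gland":
        inst = fuse_gland_contour(maps, cfg)
    elif approach == "stroma":
        inst = gland_from_stroma(maps, cfg, tile=tile,
                                 white_threshold=white_threshold)
    else:
        raise InvalidParameterError(f"unknown approach {approach!r}")
    inst = clean_mask(inst, cfg)
    if cfg.apply_crf and tile is not None and inst.max() > 0:
        soft = np.where(inst > 0, 0.9, 0.1)
        refined = crf_refine(tile, soft, cfg) >= 0.5
        if refined.any():
            _, (ir, ic) = ndimage.distance_transform_edt(
                inst == 0, return_indices=True)
            inst = np.where(refined, inst[ir, ic], 0)
            inst = clean_mask(inst, cfg)
    return inst
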