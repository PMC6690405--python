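"""Seeded generator of H&E-like tissue tiles with exact ground truth.

Each tile contains ring-shaped glandular epithelium (hematoxylin-dense cell
rings around white lumina), textured eosin-dense stroma between glands, and
at least one white background region, rendered through a known two-stain
Beer–Lambert color model (OD = densities · basis).  Because the geometry is
known exactly, the generator serves as the oracle for every downstream
stage: mask derivation, post-processing round trips, and desk-scale
end-to-end training.

Gland outlines are ellipses perturbed by low-frequency radial harmonics
(3–5 cycles); the ``morphology`` flag switches between benign-like regular
rings and malignant-like irregular ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon

from . import io
from .errors import InvalidParameterError, PlacementError
from .stain import REFERENCE_HE_BASIS, StainBasis


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; the defaults render a 480×480 training-size tile."""

    tile_size: int = 480
    n_glands: int = 8
    gland_radius_range: tuple[float, float] = (35.0, 70.0)
    lumen_fraction: float = 0.35
    epithelium_density: float = 1.0
    stroma_density: float = 0.55
    noise_sd: float = 3.0
    stain_basis: StainBasis = field(
        default_factory=lambda: StainBasis(REFERENCE_HE_BASIS, source_id="reference")
    )
    seed: int = 0
    morphology: str = "benign"  # "benign" | "malignant"

    def __post_init__(self):
        if self.n_glands < 0:
            raise InvalidParameterError("n_glands must be >= 0")
        if self.gland_radius_range[0] < 4:
            raise InvalidParameterError("gland radii must be >= 4 px")
        if not (0 <= self.lumen_fraction < 1):
            raise InvalidParameterError("lumen_fraction must lie in [0, 1)")
        if self.epithelium_density < 0 or self.stroma_density < 0:
            raise InvalidParameterError("stain densities must be >= 0")
        if self.morphology not in ("benign", "malignant"):
            raise InvalidParameterError(f"unknown morphology {self.morphology!r}")


def _gland_outline(rng: np.random.Generator, cy: float, cx: float, r0: float,
                   aspect: float, irregularity: float, n_theta: int = 180
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Radial-harmonic-perturbed ellipse outline (rows, cols)."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    radial = np.ones_like(theta)
    for k in rng.choice(np.arange(3, 6), size=2, replace=False):
        amp = irregularity * rng.uniform(0.3, 1.0)
        radial += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    radial = np.clip(radial, 0.4, 1.8)
    phi = rng.uniform(0, np.pi)
    a, b = r0 * aspect, r0 / aspect
    x = a * radial * np.cos(theta)
    y = b * radial * np.sin(theta)
    rows = cy + x * np.sin(phi) + y * np.cos(phi)
    cols = cx + x * np.cos(phi) - y * np.sin(phi)
    return rows, cols


def _rasterize(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]
               ) -> np.ndarray:
    rr, cc = polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_tissue(params: SynthParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic H&E tile; returns (RGB uint8 tile, instance mask).

    Fully reproducible per ``params.seed``.  Raises a placement error when
    the requested gland count cannot be placed without overlap.
    """
    rng = np.random.default_rng(params.seed)
    n = params.tile_size
    shape = (n, n)
    inst = np.zeros(shape, dtype=np.int32)
    lumen = np.zeros(shape, dtype=bool)

    irregularity = 0.05 if params.morphology == "benign" else 0.16
    occupied = np.zeros(shape, dtype=bool)

    # reserve a white background blob (an ellipse near a random corner)
    corner = rng.integers(0, 4)
    cy = (0.12 if corner < 2 else 0.88) * n
    cx = (0.12 if corner % 2 == 0 else 0.88) * n
    wr, wc = _gland_outline(rng, cy, cx, r0=0.16 * n, aspect=rng.uniform(1.0, 1.4),
                            irregularity=0.08)
    white_bg = _rasterize(wr, wc, shape)
    occupied |= ndimage.binary_dilation(white_bg, iterations=3)

    placed = 0
    attempts = 0
    max_attempts = 300 * max(params.n_glands, 1)
    while placed < params.n_glands:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {placed}/{params.n_glands} glands "
                f"after {attempts} attempts"
            )
        attempts += 1
        r0 = rng.uniform(*params.gland_radius_range)
        cy = rng.uniform(r0, n - r0)
        cx = rng.uniform(r0, n - r0)
        rows, cols = _gland_outline(rng, cy, cx, r0,
                                    aspect=rng.uniform(1.0, 1.5),
                                    irregularity=irregularity)
        gmask = _rasterize(rows, cols, shape)
        if gmask.sum() < 50 or (gmask & occupied).any():
            continue
        placed += 1
        inst[gmask] = placed
        # lumen: shrunk copy of the same outline (area fraction = lumen_fraction)
        s = np.sqrt(params.lumen_fraction)
        lrows = cy + (rows - cy) * s
        lcols = cx + (cols - cx) * s
        lmask = _rasterize(lrows, lcols, shape) & gmask
        lumen |= lmask
        occupied |= ndimage.binary_dilation(gmask, iterations=4)

    gland = inst > 0
    epithelium = gland & ~lumen
    stroma = ~gland & ~white_bg

    # stain density maps (hematoxylin, eosin)
    dens = np.zeros((n, n, 2), dtype=np.float64)
    # anisotropic band-pass texture for the stroma eosin channel
    noise = rng.standard_normal(shape)
    ang_sigma = rng.uniform(1.0, 3.0)
    texture = ndimage.gaussian_filter(noise, sigma=(ang_sigma, 4.5))
    texture = texture - ndimage.gaussian_filter(noise, sigma=(8, 8))
    t_sd = texture.std() or 1.0
    texture = np.clip(1.0 + 0.35 * texture / t_sd, 0.6, 1.4)
    dens[..., 0][epithelium] = params.epithelium_density * rng.uniform(
        0.85, 1.15, size=int(epithelium.sum()))
    dens[..., 1][epithelium] = 0.30 * params.stroma_density
    dens[..., 0][stroma] = 0.12 * params.epithelium_density
    dens[..., 1][stroma] = params.stroma_density * texture[stroma]

    od = dens.reshape(-1, 2) @ params.stain_basis.rows
    rgb = 256.0 * np.power(10.0, -od).reshape(n, n, 3) - 1.0
    rgb = rgb + rng.normal(0.0, params.noise_sd, size=rgb.shape)
    tile = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return tile, inst.astype(np.int64)


def true_partition(inst: np.ndarray, params: SynthParams) -> dict[str, np.ndarray]:
    """The generator's own gland/stroma/white partition for a generated tile.

    Re-derives the white background blob from the same seed, so it matches
    :func:`generate_tissue` exactly (glands take precedence over white).
    """
    rng = np.random.default_rng(params.seed)
    n = params.tile_size
    corner = rng.integers(0, 4)
    cy = (0.12 if corner < 2 else 0.88) * n
    cx = (0.12 if corner % 2 == 0 else 0.88) * n
    wr, wc = _gland_outline(rng, cy, cx, r0=0.16 * n, aspect=rng.uniform(1.0, 1.4),
                            irregularity=0.08)
    white_bg = _rasterize(wr, wc, (n, n))
    gland = inst > 0
    white = white_bg & ~gland
    stroma = ~gland & ~white
    return {"gland": gland.astype(np.uint8), "stroma": stroma.astype(np.uint8),
            "white": white.astype(np.uint8)}


def generate_dataset(params: SynthParams, n_tiles: int, out_dir: str | Path,
                     morphology_mix: float = 0.5) -> pd.DataFrame:
    """Write ``n_tiles`` (image, mask) pairs plus a manifest CSV.

    Tile ``i`` uses seed ``params.seed + i``; tiles alternate between benign
    and malignant morphology according to ``morphology_mix`` (the fraction of
    benign tiles), keeping the later stratified train/validation split
    balanced.  Returns the manifest as a DataFrame (also saved as
    ``manifest.csv``).
    """
    if n_tiles < 1:
        raise InvalidParameterError("n_tiles must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(exist_ok=True)
        (out_dir / "annotations").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    n_benign = int(round(morphology_mix * n_tiles))
    for i in range(n_tiles):
        morph = "benign" if i < n_benign else "malignant"
        p = replace(params, seed=params.seed + i, morphology=morph)
        tile, inst = generate_tissue(p)
        img_path = out_dir / "images" / f"tile_{i:04d}.png"
        ann_path = out_dir / "annotations" / f"tile_{i:04d}.png"
        io.write_image(img_path, tile)
        io.write_mask(ann_path, inst)
        rows.append({
            "image": str(img_path), "annotation": str(ann_path),
            "split": "", "morphology": morph,
            "n_glands": int(inst.max()), "seed": p.seed,
        })
    manifest = pd.DataFrame(rows)
    io.save_manifest(out_dir / "manifest.csv", manifest)
    return manifest
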