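"""Structure-preserving H&E stain normalization by sparse stain separation.

Light transmitted through stained tissue follows the Beer–Lambert law, so
stain contributions are additive in optical-density (OD) space.  Each RGB
tile is decomposed as

    OD  ≈  C · M

where ``M`` is a 2×3 non-negative, row-unit-norm *stain color basis*
(hematoxylin row first, eosin row second) and ``C`` the per-pixel
non-negative, sparse *stain density maps*.  Normalizing an image means
re-rendering its own densities with the basis (and density scale) of a
chosen target image: color moves to the target's appearance while the
tissue structure encoded in ``C`` is untouched.

The basis is estimated by seeded sparse dictionary learning with two atoms
constrained non-negative; densities are recovered by an exact closed-form
two-variable non-negative least squares, vectorised over pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import DictionaryLearning
from sklearn.exceptions import ConvergenceWarning

from .errors import InsufficientTissueError, InvalidBasisError, InvalidParameterError

#: OD norm below which a pixel is treated as near-white background and
#: excluded from basis fitting.
TISSUE_OD_THRESHOLD = 0.15

#: Minimum number of tissue pixels required to fit a basis.
MIN_TISSUE_PIXELS = 100

#: Pixels subsampled for dictionary learning (keeps fitting O(1) in tile size).
MAX_FIT_PIXELS = 5000

#: Widely used reference H&E absorption directions (RGB optical density),
#: normalized to unit rows; handy as a generator default and a sanity anchor.
REFERENCE_HE_BASIS = np.array(
    [[0.650, 0.704, 0.286],
     [0.072, 0.990, 0.105]], dtype=np.float64
)
REFERENCE_HE_BASIS /= np.linalg.norm(REFERENCE_HE_BASIS, axis=1, keepdims=True)


@dataclass(frozen=True)
class StainBasis:
    """A 2×3 stain color basis in OD space, hematoxylin row first."""

    rows: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.shape != (2, 3):
            raise InvalidBasisError(f"stain basis must be 2x3, got {rows.shape}")
        if np.any(rows < -1e-9):
            raise InvalidBasisError("stain basis entries must be non-negative")
        norms = np.linalg.norm(rows, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidBasisError(f"stain basis rows must be unit norm, got {norms}")
        object.__setattr__(self, "rows", rows)


def order_hematoxylin_first(rows: np.ndarray) -> np.ndarray:
    """Resolve the factorization's permutation ambiguity.

    The hematoxylin direction absorbs more blue light than eosin, so the row
    with the larger blue-channel OD component is placed first.
    """
    rows = np.asarray(rows, dtype=np.float64)
    if rows[0, 2] >= rows[1, 2]:
        return rows
    return rows[::-1].copy()


def rgb_to_od(tile: np.ndarray, background_intensity: float = 255.0,
              eps: float = 1.0) -> np.ndarray:
    """Convert an RGB tile to optical density: OD = -log10((v+eps)/(bg+eps)).

    A pixel at the background intensity maps to OD 0 exactly; ``eps`` keeps
    the log finite at v = 0.
    """
    if background_intensity <= 0:
        raise InvalidParameterError("background_intensity must be positive")
    v = np.asarray(tile, dtype=np.float64)
    od = -np.log10((v + eps) / (background_intensity + eps))
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0,
              eps: float = 1.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded and clipped to uint8."""
    if background_intensity <= 0:
        raise InvalidParameterError("background_intensity must be positive")
    v = (background_intensity + eps) * np.power(10.0, -np.asarray(od)) - eps
    return np.clip(np.rint(v), 0, 255).astype(np.uint8)


def _tissue_pixels(od_flat: np.ndarray) -> np.ndarray:
    return np.linalg.norm(od_flat, axis=1) >= TISSUE_OD_THRESHOLD


def estimate_stain_basis(od: np.ndarray, sparsity_weight: float = 0.1,
                         seed: int = 0, source_id: str = "") -> StainBasis:
    """Estimate the 2-row stain basis of an OD image.

    Near-white pixels (OD norm < 0.15) are excluded, a seeded subsample of at
    most 5000 tissue pixels is factorised by sparse dictionary learning with
    two non-negative atoms, and the resulting rows are unit-normalized and
    ordered hematoxylin-first.  Deterministic given ``seed``.
    """
    od_flat = np.asarray(od, dtype=np.float64).reshape(-1, 3)
    tissue = od_flat[_tissue_pixels(od_flat)]
    if tissue.shape[0] < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels (need >= {MIN_TISSUE_PIXELS})"
        )
    rng = np.random.default_rng(seed)
    if tissue.shape[0] > MAX_FIT_PIXELS:
        idx = rng.choice(tissue.shape[0], MAX_FIT_PIXELS, replace=False)
        tissue = tissue[idx]
    dl = DictionaryLearning(
        n_components=2,
        alpha=sparsity_weight,
        fit_algorithm="cd",
        transform_algorithm="lasso_cd",
        positive_code=True,
        positive_dict=True,
        max_iter=200,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        # the sparse coder's duality-gap warning fires at tolerances far
        # below the 1e-3 OD resolution that matters here
        warnings.simplefilter("ignore", ConvergenceWarning)
        dl.fit(tissue)
    rows = np.asarray(dl.components_, dtype=np.float64)
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms < 1e-8):
        raise InsufficientTissueError("degenerate stain atom (zero norm); "
                                      "tile may contain a single stain only")
    rows = rows / norms[:, None]
    rows = order_hematoxylin_first(rows)
    return StainBasis(rows=rows, source_id=source_id)


def compute_densities(od: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Per-pixel non-negative least-squares densities: od ≈ densities · basis.

    For two stains the NNLS has a closed form: take the unconstrained normal
    equation solution; wherever a coordinate goes negative, fall back to the
    better of the two single-stain projections (clamped at zero).  Exact, and
    vectorised over all pixels.
    """
    od = np.asarray(od, dtype=np.float64)
    shape = od.shape[:-1]
    X = od.reshape(-1, 3)
    M = basis.rows
    G = M @ M.T
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    if det < 1e-8:
        raise InvalidBasisError("stain basis is rank-deficient")
    b = X @ M.T  # (N, 2)
    # unconstrained solution of G c = b
    inv = np.array([[G[1, 1], -G[0, 1]], [-G[1, 0], G[0, 0]]]) / det
    c = b @ inv.T
    neg = (c[:, 0] < 0) | (c[:, 1] < 0)
    if np.any(neg):
        bn = b[neg]
        c1 = np.maximum(bn[:, 0] / G[0, 0], 0.0)  # stain 1 only
        c2 = np.maximum(bn[:, 1] / G[1, 1], 0.0)  # stain 2 only
        # residual^2 up to the constant ||od||^2: -2 c.b + c^T G c
        r1 = -2 * c1 * bn[:, 0] + c1 * c1 * G[0, 0]
        r2 = -2 * c2 * bn[:, 1] + c2 * c2 * G[1, 1]
        use1 = r1 <= r2
        cn = np.zeros_like(bn)
        cn[use1, 0] = c1[use1]
        cn[~use1, 1] = c2[~use1]
        c[neg] = cn
    return np.maximum(c, 0.0).reshape(*shape, 2)


def density_scale(densities: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Robust per-stain density scale: the given percentile over all pixels."""
    flat = np.asarray(densities, dtype=np.float64).reshape(-1, 2)
    return np.percentile(flat, percentile, axis=0)


def stain_stats(target: np.ndarray, sparsity_weight: float = 0.1, seed: int = 0,
                source_id: str = "") -> tuple[StainBasis, np.ndarray]:
    """Basis and 99th-percentile density scale of a target (reference) tile."""
    od = rgb_to_od(target)
    basis = estimate_stain_basis(od, sparsity_weight=sparsity_weight, seed=seed,
                                 source_id=source_id)
    scale = density_scale(compute_densities(od, basis))
    return basis, scale


def normalize_image(source: np.ndarray, target_basis: StainBasis,
                    target_density_scale: np.ndarray | None = None,
                    sparsity_weight: float = 0.1, seed: int = 0) -> np.ndarray:
    """Map a source tile to the target's stain appearance.

    The source's own basis and densities are estimated, each stain's density
    channel is rescaled so its 99th percentile matches the target's, and the
    densities are recombined with the target basis.  Annotations are never
    touched: the output has the source's shape and structure.
    """
    od = rgb_to_od(source)
    src_basis = estimate_stain_basis(od, sparsity_weight=sparsity_weight, seed=seed)
    dens = compute_densities(od, src_basis)
    if target_density_scale is not None:
        src_scale = density_scale(dens)
        factor = np.where(src_scale > 1e-8,
                          np.asarray(target_density_scale, dtype=np.float64)
                          / np.maximum(src_scale, 1e-8),
                          1.0)
        dens = dens * factor
    od_new = dens.reshape(-1, 2) @ target_basis.rows
    return od_to_rgb(od_new.reshape(source.shape))
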