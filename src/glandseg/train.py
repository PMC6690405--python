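"""Joint training of the dual-decoder network.

The loss is

    L_total = α·L_gland + (1−α)·L_contour + λ‖w‖²

with binary cross-entropy terms against the sigmoid outputs, α = 0.5 chosen
by cross-validation, and L2 weight decay λ = 1e-4 over convolution kernels.
Optimization uses Adam (lr 1e-3, momentum decay rates 0.90/0.99), batch
size 4, epochs of 200 mini-batches sampled with replacement, the learning
rate halved when validation loss fails to improve for 5 epochs, and the
minimum-validation-loss checkpoint selected as the final model.

Tiles and targets are resized to the network input size (bilinear for
images, nearest for masks), augmented on the fly (flips, rotation, elastic
and perspective transformation, Gaussian noise — the same spatial transform
applied to image and masks), and standardized with per-channel mean/sd
statistics computed across all training images.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import ProjectiveTransform, resize

from . import io, masks
from .errors import (DataError, DegenerateStatsError, DivergenceError,
                     InvalidParameterError, ShapeError)
from .model import DenseUNet, ModelConfig, ProbabilityMaps, build_dense_unet
from .nn import Adam, ReduceLROnPlateau, bce_with_logits
from .nn.tensor import Tensor

log = logging.getLogger("glandseg")

BCE_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.5
    weight_decay: float = 1e-4

    def __post_init__(self):
        if not (0 <= self.alpha <= 1):
            raise InvalidParameterError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    betas: tuple[float, float] = (0.90, 0.99)
    batch_size: int = 4
    epochs: int = 40
    steps_per_epoch: int = 200
    plateau_patience: int = 5
    lr_factor: float = 0.5
    val_fraction: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class NormalizationStats:
    mean: np.ndarray
    sd: np.ndarray


@dataclass(frozen=True)
class AugmentParams:
    """Probabilities and magnitudes of the five augmentation transforms."""

    p_flip: float = 0.5
    p_rotate: float = 0.5
    max_angle_deg: float = 45.0
    p_elastic: float = 0.25
    elastic_alpha: float = 10.0
    elastic_sigma: float = 8.0
    p_perspective: float = 0.25
    perspective_jitter: float = 0.05
    p_noise: float = 0.25
    noise_sd: float = 5.0


IDENTITY_AUGMENT = AugmentParams(p_flip=0, p_rotate=0, p_elastic=0,
                                 p_perspective=0, p_noise=0)


def combined_loss(pred: ProbabilityMaps, target: masks.TargetPair,
                  weights_norm: float = 0.0,
                  cfg: LossConfig = LossConfig()) -> float:
    """α·BCE(object) + (1−α)·BCE(contour) + λ·‖w‖² on probability maps."""
    if weights_norm < 0:
        raise InvalidParameterError("weights_norm must be >= 0")
    if (pred.object_prob.shape != target.object_mask.shape
            or pred.contour_prob.shape != target.contour_mask.shape):
        raise ShapeError("prediction and target shapes differ")

    def bce(p, t):
        p = np.clip(np.asarray(p, dtype=np.float64), BCE_EPS, 1 - BCE_EPS)
        t = np.asarray(t, dtype=np.float64)
        return float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))

    a = cfg.alpha
    return (a * bce(pred.object_prob, target.object_mask)
            + (1 - a) * bce(pred.contour_prob, target.contour_mask)
            + cfg.weight_decay * weights_norm)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _spatial_transform(arrays: list[np.ndarray], orders: list[int],
                       rng: np.random.Generator, params: AugmentParams
                       ) -> list[np.ndarray]:
    """Apply one jointly sampled flip/rotation/perspective/elastic transform
    to every array (same geometry, per-array interpolation order)."""
    h, w = arrays[0].shape[:2]
    flip_h = rng.random() < params.p_flip
    flip_v = rng.random() < params.p_flip
    do_rot = rng.random() < params.p_rotate
    angle = np.deg2rad(rng.uniform(-params.max_angle_deg, params.max_angle_deg))
    do_persp = rng.random() < params.p_perspective
    jitter = rng.uniform(-params.perspective_jitter, params.perspective_jitter,
                         size=(4, 2)) * [w, h]
    do_elastic = rng.random() < params.p_elastic
    # displacement field drawn unconditionally to keep the stream aligned
    disp = rng.standard_normal((2, h, w))

    matrix = np.eye(3)
    if do_rot:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, cx - c * cx + s * cy],
                        [s, c, cy - s * cx - c * cy],
                        [0, 0, 1]])
        matrix = rot @ matrix
    if do_persp:
        src = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]],
                       dtype=float)
        try:
            tf = ProjectiveTransform.from_estimate(src, src + jitter)
        except AttributeError:  # scikit-image < 0.26
            tf = ProjectiveTransform()
            tf = tf if tf.estimate(src, src + jitter) else None
        if tf:  # a failed estimation is falsy
            matrix = tf.params @ matrix

    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    # output->input mapping: invert the forward (x=col, y=row) matrix
    inv = np.linalg.inv(matrix)
    x = inv[0, 0] * cols + inv[0, 1] * rows + inv[0, 2]
    y = inv[1, 0] * cols + inv[1, 1] * rows + inv[1, 2]
    z = inv[2, 0] * cols + inv[2, 1] * rows + inv[2, 2]
    x, y = x / z, y / z
    if do_elastic:
        dy = ndimage.gaussian_filter(disp[0], params.elastic_sigma)
        dx = ndimage.gaussian_filter(disp[1], params.elastic_sigma)
        for d in (dy, dx):
            sd = d.std()
            if sd > 0:
                d *= params.elastic_alpha / (3 * sd)
        y = y + dy
        x = x + dx
    identity = not (do_rot or do_persp or do_elastic)

    out = []
    for arr, order in zip(arrays, orders):
        res = arr
        if not identity:
            if res.ndim == 3:
                res = np.stack([ndimage.map_coordinates(
                    res[..., ch].astype(np.float64), [y, x], order=order,
                    mode="reflect") for ch in range(res.shape[2])], axis=-1)
            else:
                res = ndimage.map_coordinates(res.astype(np.float64), [y, x],
                                              order=order, mode="reflect")
        if flip_h:
            res = res[:, ::-1]
        if flip_v:
            res = res[::-1]
        out.append(np.ascontiguousarray(res))
    return out


def augment_pair(tile: np.ndarray, target: masks.TargetPair, seed: int,
                 params: AugmentParams = AugmentParams()
                 ) -> tuple[np.ndarray, masks.TargetPair]:
    """Seeded joint augmentation of a tile and its supervision targets.

    The spatial transform is identical for image and masks; masks use
    nearest-neighbour resampling and stay binary; Gaussian noise touches the
    image only.
    """
    if tile.shape[:2] != target.object_mask.shape:
        raise ShapeError("tile and target shapes differ")
    rng = np.random.default_rng(seed)
    img, obj, cnt = _spatial_transform(
        [np.asarray(tile, dtype=np.float64),
         np.asarray(target.object_mask), np.asarray(target.contour_mask)],
        orders=[1, 0, 0], rng=rng, params=params)
    if rng.random() < params.p_noise:
        img = img + rng.normal(0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255)
    new_target = masks.TargetPair(
        object_mask=(obj > 0.5).astype(np.uint8),
        contour_mask=(cnt > 0.5).astype(np.uint8),
        approach=target.approach)
    return img, new_target


# ---------------------------------------------------------------------------
# normalization statistics
# ---------------------------------------------------------------------------

def compute_normalization_stats(tiles: list[np.ndarray]) -> NormalizationStats:
    """Per-channel mean/sd (population) over all pixels of all training tiles."""
    if not tiles:
        raise DataError("need at least one training tile")
    flat = np.concatenate([np.asarray(t, dtype=np.float64).reshape(-1, 3)
                           for t in tiles], axis=0)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    if np.any(sd <= 0):
        raise DegenerateStatsError(f"zero-variance channel(s): sd={sd}")
    return NormalizationStats(mean=mean, sd=sd)


def standardize(tile: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (np.asarray(tile, dtype=np.float64) - stats.mean) / stats.sd


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _resize_pair(tile: np.ndarray, inst: np.ndarray, size: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Resize image (bilinear) and instance mask (nearest) to size×size."""
    if tile.shape[0] != size or tile.shape[1] != size:
        tile = resize(tile.astype(np.float64), (size, size), order=1,
                      preserve_range=True, anti_aliasing=True)
        inst = resize(inst, (size, size), order=0, preserve_range=True,
                      anti_aliasing=False).astype(inst.dtype)
    return np.asarray(tile, dtype=np.float64), inst


def split_manifest(manifest: pd.DataFrame, val_fraction: float, seed: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/val split of manifest rows, stratified on the
    morphology tag (mirrors a benign/malignant-balanced split)."""
    rng = np.random.default_rng(seed)
    morph = manifest.get("morphology", pd.Series([""] * len(manifest)))
    train_idx, val_idx = [], []
    for _, group in manifest.groupby(morph.fillna("").astype(str)):
        idx = group.index.to_numpy()
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


@dataclass
class TrainResult:
    model: DenseUNet
    stats: NormalizationStats
    history: pd.DataFrame
    best_epoch: int
    train_indices: np.ndarray = field(default_factory=lambda: np.array([]))
    val_indices: np.ndarray = field(default_factory=lambda: np.array([]))


def _forward_loss(model: DenseUNet, batch_x: np.ndarray, batch_obj: np.ndarray,
                  batch_cnt: np.ndarray, alpha: float) -> Tensor:
    x = Tensor(batch_x)
    obj_logit, cnt_logit = model.forward_logits(x)
    from .nn.tensor import add, scale
    return add(scale(bce_with_logits(obj_logit, batch_obj), alpha),
               scale(bce_with_logits(cnt_logit, batch_cnt), 1 - alpha))


def train_model(manifest: pd.DataFrame, approach: str,
                model_cfg: ModelConfig = ModelConfig(),
                train_cfg: TrainConfig = TrainConfig(),
                loss_cfg: LossConfig = LossConfig(),
                augment: AugmentParams = AugmentParams(),
                contour_thickness: int = masks.DEFAULT_CONTOUR_THICKNESS,
                log_csv: str | Path | None = None) -> TrainResult:
    """Train the dual-decoder network for one approach (gland or stroma).

    Loads (image, instance mask) pairs from the manifest, derives the
    approach's supervision targets, resizes everything to the model input
    size, and runs seeded mini-batch training with on-the-fly augmentation.
    Returns the minimum-validation-loss model plus a per-epoch history.
    """
    if manifest is None or len(manifest) == 0:
        raise DataError("empty training manifest")
    size = model_cfg.input_size
    tiles, objs, cnts = [], [], []
    for _, row in manifest.iterrows():
        tile = io.read_image(row["image"])
        inst = io.read_mask(row["annotation"])
        tile, inst = _resize_pair(tile, inst, size)
        pair = masks.targets_for_approach(tile, inst, approach,
                                          thickness=contour_thickness)
        tiles.append(tile)
        objs.append(pair.object_mask.astype(np.float32))
        cnts.append(pair.contour_mask.astype(np.float32))

    train_idx, val_idx = split_manifest(manifest, train_cfg.val_fraction,
                                        train_cfg.seed)
    if len(train_idx) == 0:
        raise DataError("train split is empty")
    stats = compute_normalization_stats([tiles[i] for i in train_idx])

    model = build_dense_unet(model_cfg)
    optimizer = Adam(list(model.parameters()), lr=train_cfg.lr,
                     betas=train_cfg.betas,
                     weight_decay=loss_cfg.weight_decay)
    scheduler = ReduceLROnPlateau(optimizer, factor=train_cfg.lr_factor,
                                  patience=train_cfg.plateau_patience)
    rng = np.random.default_rng(train_cfg.seed + 1)

    def batch_arrays(indices, augment_seeds=None):
        xs, os_, cs = [], [], []
        for j, i in enumerate(indices):
            if augment_seeds is not None:
                pair = masks.TargetPair(objs[i].astype(np.uint8),
                                        cnts[i].astype(np.uint8), approach)
                img, pair = augment_pair(tiles[i], pair, int(augment_seeds[j]),
                                         augment)
                xs.append(standardize(img, stats))
                os_.append(pair.object_mask)
                cs.append(pair.contour_mask)
            else:
                xs.append(standardize(tiles[i], stats))
                os_.append(objs[i])
                cs.append(cnts[i])
        x = np.stack(xs).transpose(0, 3, 1, 2).astype(np.float32)
        o = np.stack(os_).astype(np.float32)[:, None]
        c = np.stack(cs).astype(np.float32)[:, None]
        return x, o, c

    def validation_loss() -> float:
        model.eval()
        total, count = 0.0, 0
        for start in range(0, len(val_idx), 8):
            chunk = val_idx[start:start + 8]
            x, o, c = batch_arrays(chunk)
            loss = _forward_loss(model, x, o, c, loss_cfg.alpha)
            total += float(loss.data) * len(chunk)
            count += len(chunk)
        model.train()
        return total / max(count, 1)

    history_rows = []
    best_val = np.inf
    best_state = copy.deepcopy(model.state_dict())
    best_epoch = 0
    for epoch in range(1, train_cfg.epochs + 1):
        model.train()
        train_loss_sum = 0.0
        for _ in range(train_cfg.steps_per_epoch):
            batch = rng.choice(train_idx, size=train_cfg.batch_size,
                               replace=True)
            seeds = rng.integers(0, 2**31, size=train_cfg.batch_size)
            x, o, c = batch_arrays(batch, augment_seeds=seeds)
            optimizer.zero_grad()
            loss = _forward_loss(model, x, o, c, loss_cfg.alpha)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}",
                                      epoch=epoch)
            loss.backward()
            optimizer.step()
            train_loss_sum += float(loss.data)
        train_loss = train_loss_sum / max(train_cfg.steps_per_epoch, 1)
        val_loss = validation_loss() if len(val_idx) else train_loss
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}",
                                  epoch=epoch)
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
            best_epoch = epoch
        history_rows.append({"epoch": epoch, "train_loss": train_loss,
                             "val_loss": val_loss, "lr": optimizer.lr})
        scheduler.step(val_loss)
        log.info("epoch %d/%d train %.4f val %.4f lr %.2e", epoch,
                 train_cfg.epochs, train_loss, val_loss, optimizer.lr)

    model.load_state_dict(best_state)
    model.eval()
    history = pd.DataFrame(history_rows)
    if log_csv is not None:
        history.to_csv(Path(log_csv), index=False)
    return TrainResult(model=model, stats=stats, history=history,
                       best_epoch=best_epoch, train_indices=train_idx,
                       val_indices=val_idx)
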