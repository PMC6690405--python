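"""End-to-end orchestration: synth/normalize → masks → train → predict →
postprocess → evaluate, all under one run directory with a resolved config
snapshot, a line-oriented log, and full seed-driven reproducibility."""

from __future__ import annotations

import dataclasses
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, masks, metrics, postprocess, stain, synth, train
from .config import RunConfig, save_config
from .errors import DataError
from .model import load_checkpoint, predict_maps, save_checkpoint

log = logging.getLogger("glandseg")


def setup_logging(level: str = "INFO", logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
        handlers=handlers,
        force=True,
    )


class StageFailure(RuntimeError):
    """Wraps any stage error with the stage name for the CLI diagnostic."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with context
                raise StageFailure(name, exc) from exc
            log.info("stage %s: done", name)
            return result
        return wrapper
    return decorator


@_stage("synth")
def _synth_stage(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    params = dataclasses.replace(config.synth, seed=config.stage_seed("synth"))
    n_total = config.n_tiles + config.n_test_tiles
    manifest = synth.generate_dataset(params, n_total, run_dir / "data")
    manifest = manifest.copy()
    # held-out test tiles: the tail of each morphology stratum
    manifest["split"] = "trainval"
    for _, group in manifest.groupby("morphology"):
        k = int(round(config.n_test_tiles * len(group) / n_total))
        manifest.loc[group.index[len(group) - k:], "split"] = "test"
    io.save_manifest(run_dir / "data" / "manifest.csv", manifest)
    return manifest


@_stage("normalize")
def _normalize_stage(config: RunConfig, manifest: pd.DataFrame, run_dir: Path
                     ) -> pd.DataFrame:
    target_path = config.stain.target or manifest.iloc[0]["image"]
    target = io.read_image(target_path)
    seed = config.stage_seed("stain")
    basis, scale = stain.stain_stats(target, config.stain.sparsity_weight,
                                     seed=seed, source_id=str(target_path))
    out_dir = run_dir / "normalized"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    new_paths = []
    for _, row in manifest.iterrows():
        tile = io.read_image(row["image"])
        norm = stain.normalize_image(tile, basis, scale,
                                     config.stain.sparsity_weight, seed=seed)
        out_path = out_dir / Path(row["image"]).name
        io.write_image(out_path, norm)
        new_paths.append(str(out_path))
    manifest["image"] = new_paths
    io.save_manifest(run_dir / "normalized" / "manifest.csv", manifest)
    return manifest


@_stage("train")
def _train_stage(config: RunConfig, manifest: pd.DataFrame, approach: str,
                 run_dir: Path) -> train.TrainResult:
    trainval = manifest[manifest["split"] != "test"].reset_index(drop=True)
    if trainval.empty:
        raise DataError("no training tiles after the test split")
    train_cfg = dataclasses.replace(config.train,
                                    seed=config.stage_seed("train"))
    result = train.train_model(
        trainval, approach,
        model_cfg=config.model, train_cfg=train_cfg, loss_cfg=config.loss,
        augment=config.augment,
        contour_thickness=config.masks.contour_thickness,
        log_csv=run_dir / f"training_{approach}.csv")
    save_checkpoint(run_dir / f"model_{approach}.npz", result.model,
                    extra={"approach": approach,
                           "norm_mean": list(result.stats.mean),
                           "norm_sd": list(result.stats.sd),
                           "best_epoch": result.best_epoch})
    return result


@_stage("predict+postprocess")
def _predict_stage(config: RunConfig, manifest: pd.DataFrame, approach: str,
                   result: train.TrainResult, run_dir: Path) -> Path:
    test = manifest[manifest["split"] == "test"]
    if test.empty:
        raise DataError("no test tiles")
    pred_dir = run_dir / f"predictions_{approach}"
    truth_dir = run_dir / "truth"
    pred_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    size = config.model.input_size
    for _, row in test.iterrows():
        tile = io.read_image(row["image"])
        inst = io.read_mask(row["annotation"])
        tile_r, inst_r = train._resize_pair(tile, inst, size)
        maps = predict_maps(result.model, train.standardize(tile_r, result.stats))
        seg = postprocess.segment(maps, approach, tile=tile_r,
                                  cfg=config.postprocess,
                                  white_threshold=config.masks.white_threshold)
        stem = Path(row["image"]).stem
        io.write_mask(pred_dir / f"{stem}.png", seg)
        io.write_binary_mask(pred_dir / f"{stem}_binary.png", seg > 0)
        truth_path = truth_dir / f"{stem}.png"
        if not truth_path.exists():
            io.write_mask(truth_path, inst_r)
    return pred_dir


@_stage("evaluate")
def _evaluate_stage(pred_dir: Path, truth_dir: Path, out_csv: Path
                    ) -> metrics.EvalResult:
    # the *_binary.png copies are a CLI convenience; evaluate instance masks
    pairs = []
    for pred_path in sorted(pred_dir.glob("*.png")):
        if pred_path.stem.endswith("_binary"):
            continue
        truth = io.read_mask(truth_dir / pred_path.name) > 0
        pred = io.read_mask(pred_path) > 0
        pairs.append((pred_path.stem, truth, pred))
    result = metrics.evaluate_pairs(
        pairs, resolution=f"{pairs[0][1].shape[1]}x{pairs[0][1].shape[0]}")
    df = result.per_image.copy()
    df["hausdorff_mode"] = result.hausdorff_mode
    df["resolution"] = result.resolution
    df.to_csv(out_csv, index=False)
    return result


def run_pipeline(config: RunConfig, approach: str, run_dir: str | Path,
                 manifest_path: str | Path | None = None,
                 synthetic: bool = False) -> dict:
    """Execute the full workflow for one approach under ``run_dir``.

    Either ``synthetic=True`` (generate the dataset) or ``manifest_path``
    must be given; failing both is a data error before any compute.  Returns
    a summary dict with mean Dice/Hausdorff and artifact paths.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(config.log_level, logfile=run_dir / "run.log")
    save_config(config, run_dir / "config_resolved.yaml")
    if not synthetic and manifest_path is None:
        raise DataError("either a manifest or --synthetic is required")
    if synthetic:
        manifest = _synth_stage(config, run_dir)
    else:
        manifest = io.load_manifest(manifest_path)
        if (manifest["split"] == "test").sum() == 0:
            raise DataError("manifest must tag some rows with split='test'")
    if config.stain.enabled:
        manifest = _normalize_stage(config, manifest, run_dir)
    result = _train_stage(config, manifest, approach, run_dir)
    pred_dir = _predict_stage(config, manifest, approach, result, run_dir)
    eval_result = _evaluate_stage(pred_dir, run_dir / "truth",
                                  run_dir / f"report_{approach}.csv")
    summary = {
        "approach": approach,
        "mean_dice": eval_result.mean_dice,
        "mean_hausdorff_px": eval_result.mean_hausdorff,
        "report": str(run_dir / f"report_{approach}.csv"),
        "checkpoint": str(run_dir / f"model_{approach}.npz"),
    }
    log.info("run summary: %s", summary)
    return summary


def predict_from_checkpoint(checkpoint: str | Path, image_path: str | Path,
                            out_dir: str | Path, config: RunConfig,
                            approach: str | None = None) -> Path:
    """Single-tile inference + post-processing from a saved checkpoint."""
    model, extra = load_checkpoint(checkpoint)
    stats = train.NormalizationStats(mean=np.array(extra["norm_mean"]),
                                     sd=np.array(extra["norm_sd"]))
    approach = approach or extra.get("approach", "gland")
    tile = io.read_image(image_path)
    tile_r = train._resize_pair(tile, np.zeros(tile.shape[:2], np.int64),
                                model.config.input_size)[0]
    maps = predict_maps(model, train.standardize(tile_r, stats))
    seg = postprocess.segment(maps, approach, tile=tile_r,
                              cfg=config.postprocess,
                              white_threshold=config.masks.white_threshold)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(image_path).stem
    io.write_mask(out_dir / f"{stem}.png", seg)
    io.write_binary_mask(out_dir / f"{stem}_binary.png", seg > 0)
    np.savez_compressed(out_dir / f"{stem}_maps.npz",
                        object_prob=maps.object_prob,
                        contour_prob=maps.contour_prob)
    return out_dir / f"{stem}.png"
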