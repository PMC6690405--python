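"""Dual-decoder Dense-U-Net.

A DenseNet-style encoder — stem (7×7 stride-2 conv + 3×3 stride-2 max pool),
four dense blocks with growth-rate concatenation, and transition layers that
halve channels and average-pool stride 2 — feeds two independent, symmetric
decoders.  Each decoder alternates a reverse-transition (1×1 channel
reduction + bilinear ×2 upsampling) with a 3×3 convolution over the
concatenation of the upsampled features and the equal-resolution encoder
block output, and ends in a 1-channel sigmoid head.  One head predicts the
object (gland or stroma) probability map, the other the contour map.

The default configuration is the Dense-169 layout: blocks [6, 12, 32, 32]
with growth rate 32.  Because the stem downsamples by 4, the decoder runs
one more upsampling stage than there are dense blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import InvalidParameterError, ShapeError
from .nn.tensor import Tensor


@dataclass(frozen=True)
class ModelConfig:
    block_layers: tuple[int, ...] = (6, 12, 32, 32)
    growth_rate: int = 32
    input_size: int = 480
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    pretrained_encoder: str | None = None
    seed: int = 0

    def __post_init__(self):
        if len(self.block_layers) != 4:
            raise InvalidParameterError("block_layers must list 4 dense blocks")
        if self.input_size % 32:
            raise InvalidParameterError("input_size must be divisible by 32")
        if len(self.decoder_channels) != 5:
            raise InvalidParameterError("decoder needs 5 per-stage channel counts")


@dataclass(frozen=True)
class ProbabilityMaps:
    """Paired per-pixel object and contour probabilities in [0, 1]."""

    object_prob: np.ndarray
    contour_prob: np.ndarray


class DenseLayer(nn.Module):
    """BN-ReLU-1×1(4g) bottleneck + BN-ReLU-3×3(g); output is concatenated."""

    def __init__(self, c_in: int, growth: int, rng):
        self.bottleneck = nn.BnReluConv(c_in, 4 * growth, kernel=1, rng=rng)
        self.conv = nn.BnReluConv(4 * growth, growth, kernel=3, padding=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(self.bottleneck(x))


class DenseBlock(nn.Module):
    """Every layer sees the concatenation of all previous outputs."""

    def __init__(self, c_in: int, n_layers: int, growth: int, rng):
        self.layers = [DenseLayer(c_in + i * growth, growth, rng)
                       for i in range(n_layers)]
        self.c_in = c_in
        self.c_out = c_in + n_layers * growth

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = nn.concat([x, layer(x)], axis=1)
        return x


class DecoderStage(nn.Module):
    """Reverse transition (1×1 reduce + bilinear ×2) then 3×3 conv over the
    skip concatenation."""

    def __init__(self, c_in: int, c_skip: int, c_out: int, rng):
        self.reduce = nn.BnReluConv(c_in, c_out, kernel=1, rng=rng)
        self.fuse = nn.BnReluConv(c_out + c_skip, c_out, kernel=3, padding=1,
                                  rng=rng)
        self.c_out = c_out

    def __call__(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = self.reduce(x)
        h, w = x.shape[2] * 2, x.shape[3] * 2
        x = nn.upsample_bilinear(x, h, w)
        if skip is not None:
            x = nn.concat([x, skip], axis=1)
        return self.fuse(x)


class Decoder(nn.Module):
    def __init__(self, c_bottom: int, skip_channels: list[int],
                 widths: tuple[int, ...], rng):
        stages = []
        c = c_bottom
        for width, c_skip in zip(widths, skip_channels):
            stages.append(DecoderStage(c, c_skip, width, rng))
            c = width
        self.stages = stages
        self.head = nn.Conv2d(c, 1, kernel=1, rng=rng)

    def __call__(self, x: Tensor, skips: list[Tensor | None]) -> Tensor:
        for stage, skip in zip(self.stages, skips):
            x = stage(x, skip)
        return self.head(x)  # logits; sigmoid applied at predict time


class DenseUNet(nn.Module):
    """Encoder shared by two weight-independent decoders (object / contour)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        g = config.growth_rate
        c = 2 * g  # stem width, DenseNet convention

        self.stem_conv = nn.Conv2d(3, c, kernel=7, stride=2, padding=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c)

        self.blocks: list[DenseBlock] = []
        self.transitions: list[nn.TransitionDown] = []
        self.channel_table: list[dict] = [
            {"stage": "stem", "c_in": 3, "c_out": c, "downsample": 4}]
        for i, n_layers in enumerate(config.block_layers):
            block = DenseBlock(c, n_layers, g, rng)
            self.blocks.append(block)
            self.channel_table.append(
                {"stage": f"dense_block_{i + 1}", "c_in": c,
                 "c_out": block.c_out, "n_layers": n_layers})
            c = block.c_out
            if i < len(config.block_layers) - 1:
                self.transitions.append(nn.TransitionDown(c, c // 2, rng=rng))
                self.channel_table.append(
                    {"stage": f"transition_{i + 1}", "c_in": c, "c_out": c // 2,
                     "downsample": 2})
                c = c // 2
        self.final_bn = nn.BatchNorm2d(c)
        self.c_bottom = c

        # skip channels, deepest first: block3, block2, block1 outputs
        # (pre-transition), stem activation at /2, then none at /1
        skip_channels = [self.blocks[2].c_out, self.blocks[1].c_out,
                         self.blocks[0].c_out, 2 * g, 0]
        self.object_decoder = Decoder(c, skip_channels,
                                      config.decoder_channels, rng)
        self.contour_decoder = Decoder(c, skip_channels,
                                       config.decoder_channels, rng)

    # -- forward ------------------------------------------------------------

    def forward_logits(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ShapeError(f"input spatial size {x.shape[2:]} not divisible by 32")
        stem = nn.relu(self.stem_bn(self.stem_conv(x)))          # /2
        f = nn.max_pool(stem, kernel=3, stride=2, padding=1)     # /4
        block_outs = []
        for i, block in enumerate(self.blocks):
            f = block(f)
            block_outs.append(f)
            if i < len(self.transitions):
                f = self.transitions[i](f)
        f = nn.relu(self.final_bn(f))                            # /32
        skips = [block_outs[2], block_outs[1], block_outs[0], stem, None]
        return (self.object_decoder(f, skips),
                self.contour_decoder(f, skips))

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        return self.forward_logits(x)

    def load_encoder_weights(self, path: str | Path) -> None:
        """Optional hook: load pre-trained encoder weights from an .npz file
        whose keys match this model's encoder parameter names."""
        state = dict(np.load(Path(path)))
        encoder_keys = {k for k, _ in self.named_parameters()
                        if k.startswith(("stem_", "blocks.", "transitions.",
                                         "final_bn."))}
        self.load_state_dict({k: v for k, v in state.items()
                              if k.partition(":")[2] in encoder_keys})


def build_dense_unet(config: ModelConfig | None = None) -> DenseUNet:
    """Construct the dual-decoder Dense-U-Net (He init unless a pretrained
    encoder checkpoint is configured)."""
    config = config or ModelConfig()
    model = DenseUNet(config)
    if config.pretrained_encoder:
        model.load_encoder_weights(config.pretrained_encoder)
    return model


def predict_maps(model: DenseUNet, tile: np.ndarray) -> ProbabilityMaps:
    """Run inference on one normalized tile (H, W, 3) → probability maps.

    The tile must already carry the training normalization (float, roughly
    zero mean); spatial size must be divisible by 32.  Deterministic: batch
    norm uses running statistics.
    """
    tile = np.asarray(tile, dtype=np.float32)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ShapeError(f"expected (H, W, 3) tile, got {tile.shape}")
    model.eval()
    x = Tensor(tile.transpose(2, 0, 1)[None])
    obj_logit, cnt_logit = model.forward_logits(x)
    obj = nn.sigmoid(obj_logit).data[0, 0]
    cnt = nn.sigmoid(cnt_logit).data[0, 0]
    return ProbabilityMaps(object_prob=obj.astype(np.float64),
                           contour_prob=cnt.astype(np.float64))


# -- checkpoints -------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, model: DenseUNet,
                    extra: dict | None = None) -> None:
    """Native .npz checkpoint with a JSON header (version + config + extras)."""
    header = {
        "version": CHECKPOINT_VERSION,
        "config": {
            "block_layers": list(model.config.block_layers),
            "growth_rate": model.config.growth_rate,
            "input_size": model.config.input_size,
            "decoder_channels": list(model.config.decoder_channels),
            "seed": model.config.seed,
        },
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez_compressed(Path(path), __header__=json.dumps(header), **state)


def load_checkpoint(path: str | Path) -> tuple[DenseUNet, dict]:
    """Rebuild a model from a checkpoint; returns (model, extra header dict)."""
    data = dict(np.load(Path(path), allow_pickle=False))
    header = json.loads(str(data.pop("__header__")))
    cfg = header["config"]
    config = ModelConfig(block_layers=tuple(cfg["block_layers"]),
                         growth_rate=cfg["growth_rate"],
                         input_size=cfg["input_size"],
                         decoder_channels=tuple(cfg["decoder_channels"]),
                         seed=cfg.get("seed", 0))
    model = DenseUNet(config)
    model.load_state_dict(data)
    return model, header.get("extra", {})


def layer_table(model: DenseUNet) -> str:
    """Human-readable encoder layout + parameter count (`build-info`)."""
    lines = [f"{'stage':<16}{'c_in':>8}{'c_out':>8}"]
    for row in model.channel_table:
        lines.append(f"{row['stage']:<16}{row['c_in']:>8}{row['c_out']:>8}")
    lines.append(f"decoder widths: {model.config.decoder_channels} (x2 decoders)")
    lines.append(f"parameters: {model.parameter_count():,}")
    return "\n".join(lines)
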