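"""Segmentation networks: plain U-Net and EfficientUNet.

Two fully-convolutional 2D encoder–decoder networks ending in a 1x1
convolution and a sigmoid, so the output is a per-pixel foreground
probability map of the same spatial size as the input:

* **U-Net** — five encoder blocks (two 3x3 conv + BN + ReLU each,
  channel width doubling from ``base_filters``, 2x2 max-pool between
  levels) and a mirrored decoder (nearest 2x upsample, skip
  concatenation from the same-resolution encoder level, two convs).

* **EfficientUNet** — the same decoder idea, but the encoder is an
  EfficientNetV2-S backbone: a stride-2 stem, three Fused-MBConv stages
  and three MBConv stages with squeeze-excitation (ratio 0.25),
  exposing one feature tap per resolution halving.  Stage widths follow
  the published small-variant plan (24, 24, 48, 64, 128, 160, 256); the
  classification head (1x1 conv / pooling / FC) has no role in dense
  prediction and is dropped.

A ``width_mult`` scales every channel width (rounded to the nearest
multiple of 8, half up, minimum 8) so desk-scale instances train on one
CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import core as C
from .nn import layers as L


def round_channels(channels: float, width_mult: float = 1.0, divisor: int = 8) -> int:
    """Scale a channel count and round to the nearest multiple of 8 (half up, min 8)."""
    if width_mult <= 0:
        raise ValueError("width_mult must be > 0")
    scaled = channels * width_mult
    return max(divisor, int(np.floor(scaled / divisor + 0.5)) * divisor)


@dataclass
class StageSpec:
    operator: str  # conv | fused_mbconv | mbconv | head
    expansion: int
    kernel: int
    se_ratio: float | None
    out_channels: int
    repeats: int
    stride: int


#: EfficientNetV2-S stage table (width-1 channels; repeats follow the
#: published small variant).  The final head stage is listed for
#: completeness but not instantiated for segmentation.
EFFICIENTNETV2S_STAGES: tuple[StageSpec, ...] = (
    StageSpec("conv", 1, 3, None, 24, 1, 2),  # stem
    StageSpec("fused_mbconv", 1, 3, None, 24, 2, 1),
    StageSpec("fused_mbconv", 4, 3, None, 48, 4, 2),
    StageSpec("fused_mbconv", 4, 3, None, 64, 4, 2),
    StageSpec("mbconv", 4, 3, 0.25, 128, 6, 2),
    StageSpec("mbconv", 6, 3, 0.25, 160, 9, 1),
    StageSpec("mbconv", 6, 3, 0.25, 256, 15, 2),
    StageSpec("head", 1, 1, None, 1280, 1, 1),
)


@dataclass
class EncoderSpec:
    stages: tuple[StageSpec, ...] = EFFICIENTNETV2S_STAGES


@dataclass
class ModelConfig:
    """Architecture description for :func:`build_model`."""

    architecture: str = "unet"  # unet | efficientunet
    input_size: int = 128
    in_channels: int = 4
    base_filters: int = 32
    depth: int = 5
    width_mult: float = 1.0
    se_ratio: float = 0.25
    seed: int = 0
    encoder_repeats: tuple[int, ...] | None = None  # override per-stage repeats

    def __post_init__(self) -> None:
        if self.architecture not in ("unet", "efficientunet"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.width_mult <= 0:
            raise ValueError("width_mult must be > 0")
        if self.architecture == "unet":
            if self.input_size % (2 ** (self.depth - 1)):
                raise ValueError(
                    f"input_size {self.input_size} not divisible by 2^(depth-1)"
                )
        else:
            if self.in_channels != 3:
                raise ValueError("EfficientUNet takes three-channel combos (in_channels=3)")
            if self.input_size % 32:
                raise ValueError("EfficientUNet input_size must be divisible by 32")


# ---------------------------------------------------------------------------
# U-Net


class UNet(L.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        base = round_channels(config.base_filters, config.width_mult)
        widths = [base * 2**i for i in range(config.depth)]
        self.depth = config.depth

        self.enc_blocks = []
        cin = config.in_channels
        for w in widths:
            self.enc_blocks.append(
                [L.ConvBNAct(cin, w, 3, act="relu", rng=rng),
                 L.ConvBNAct(w, w, 3, act="relu", rng=rng)]
            )
            cin = w
        self.dec_blocks = []
        for i in range(config.depth - 2, -1, -1):  # decoder mirrors encoder
            skip_w, up_w = widths[i], widths[i + 1]
            self.dec_blocks.append(
                [L.ConvBNAct(up_w + skip_w, skip_w, 3, act="relu", rng=rng),
                 L.ConvBNAct(skip_w, skip_w, 3, act="relu", rng=rng)]
            )
        self.head = L.Conv2d(widths[0], 1, 1, bias=True, rng=rng)
        # flat list so Module.modules() sees the nested blocks
        self._all = [m for blk in self.enc_blocks + self.dec_blocks for m in blk]

    def __call__(self, x: C.Tensor) -> C.Tensor:
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            for m in blk:
                x = m(x)
            if i < self.depth - 1:
                skips.append(x)
                x = C.max_pool2(x)
        for blk, skip in zip(self.dec_blocks, reversed(skips)):
            x = C.upsample_nearest2(x)
            x = C.concat_channels(x, skip)
            for m in blk:
                x = m(x)
        return C.sigmoid(self.head(x))


# ---------------------------------------------------------------------------
# EfficientNetV2-S encoder and EfficientUNet


class EfficientNetV2SEncoder(L.Module):
    """Backbone producing one feature tap per resolution halving.

    Taps (for a 2^k input): stage 1 (1/2), stage 2 (1/4), stage 3 (1/8),
    stage 5 (1/16), stage 6 (1/32).
    """

    def __init__(self, config: ModelConfig, spec: EncoderSpec | None = None):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        spec = spec or EncoderSpec()
        stages = [s for s in spec.stages if s.operator != "head"]
        if config.encoder_repeats is not None:
            if len(config.encoder_repeats) != len(stages) - 1:
                raise ValueError("encoder_repeats must cover the six block stages")
            stages = [stages[0]] + [
                StageSpec(**{**asdict(s), "repeats": r})
                for s, r in zip(stages[1:], config.encoder_repeats)
            ]

        wm = config.width_mult
        self.stage_channels = [round_channels(s.out_channels, wm) for s in stages]
        self.blocks_per_stage: list[list[L.Module]] = []

        stem = stages[0]
        cin = config.in_channels
        self.stem = L.ConvBNAct(cin, self.stage_channels[0], stem.kernel, stem.stride,
                                act="silu", rng=rng)
        cin = self.stage_channels[0]
        for s, cout in zip(stages[1:], self.stage_channels[1:]):
            blocks = []
            for r in range(s.repeats):
                stride = s.stride if r == 0 else 1
                if s.operator == "fused_mbconv":
                    blocks.append(
                        L.FusedMBConv(cin, cout, s.expansion, s.kernel, stride,
                                      act="silu", rng=rng)
                    )
                elif s.operator == "mbconv":
                    blocks.append(
                        L.MBConv(cin, cout, s.expansion, s.kernel, stride,
                                 se_ratio=s.se_ratio or 0.0, act="silu", rng=rng)
                    )
                else:
                    raise ValueError(f"unknown operator {s.operator!r}")
                cin = cout
            self.blocks_per_stage.append(blocks)
        self._all = [b for blocks in self.blocks_per_stage for b in blocks]
        self._stage_strides = [s.stride for s in stages[1:]]
        #: channels of the taps at 1/2, 1/4, 1/8, 1/16, 1/32
        self.tap_channels = [
            self.stage_channels[1],  # after stage 1 (still 1/2)
            self.stage_channels[2],
            self.stage_channels[3],
            self.stage_channels[5],  # stage 5 keeps 1/16
            self.stage_channels[6],
        ]

    def __call__(self, x: C.Tensor) -> list[C.Tensor]:
        x = self.stem(x)
        taps = []
        for i, blocks in enumerate(self.blocks_per_stage, start=1):
            for b in blocks:
                x = b(x)
            if i in (1, 2, 3, 5, 6):
                taps.append(x)
        return taps


class EfficientUNet(L.Module):
    """EfficientNetV2-S encoder + five-block conventional conv decoder."""

    def __init__(self, config: ModelConfig, spec: EncoderSpec | None = None):
        super().__init__()
        rng = np.random.default_rng(config.seed + 1)
        self.encoder = EfficientNetV2SEncoder(config, spec)
        c1, c2, c3, c5, c6 = self.encoder.tap_channels
        # decoder widths mirror the encoder tap widths; the final
        # full-resolution block (no encoder tap left) keeps c1
        plan = [  # (upsampled-in channels, skip channels, out channels)
            (c6, c5, c5),
            (c5, c3, c3),
            (c3, c2, c2),
            (c2, c1, c1),
            (c1, 0, c1),
        ]
        self.dec_blocks = []
        for cin_up, cskip, cout in plan:
            self.dec_blocks.append(
                [L.ConvBNAct(cin_up + cskip, cout, 3, act="relu", rng=rng),
                 L.ConvBNAct(cout, cout, 3, act="relu", rng=rng)]
            )
        self.head = L.Conv2d(c1, 1, 1, bias=True, rng=rng)
        self._all = [m for blk in self.dec_blocks for m in blk]

    def __call__(self, x: C.Tensor) -> C.Tensor:
        taps = self.encoder(x)
        t1, t2, t3, t5, t6 = taps
        skips = [t5, t3, t2, t1, None]
        x = t6
        for blk, skip in zip(self.dec_blocks, skips):
            x = C.upsample_nearest2(x)
            if skip is not None:
                x = C.concat_channels(x, skip)
            for m in blk:
                x = m(x)
        return C.sigmoid(self.head(x))


# ---------------------------------------------------------------------------
# model wrapper


@dataclass
class SegmentationModel:
    """A trainable slice-to-probability-map function plus its config."""

    net: L.Module
    config: ModelConfig

    @property
    def parameter_count(self) -> int:
        return self.net.parameter_count()

    def forward(self, batch: np.ndarray) -> C.Tensor:
        """Training-mode forward on a (N, C, H, W) batch; returns the graph."""
        return self.net(C.Tensor(batch))

    def predict_proba(self, batch: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Inference on a (N, C, H, W) array -> (N, 1, H, W) probabilities."""
        batch = np.asarray(batch, dtype=np.float32)
        was_training = self.net.training
        self.net.eval()
        outs = []
        try:
            with C.no_grad():
                for i in range(0, len(batch), batch_size):
                    outs.append(self.net(C.Tensor(batch[i : i + batch_size])).data)
        finally:
            self.net.train(was_training)
        return np.concatenate(outs, axis=0)

    def save(self, path) -> Path:
        """Single-file npz checkpoint + JSON architecture sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"param_{i:04d}": p.data for i, p in enumerate(self.net.parameters())}
        arrays.update(
            {f"buffer_{i:04d}": b for i, b in enumerate(self.net.buffers())}
        )
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        cfg = asdict(self.config)
        if cfg.get("encoder_repeats") is not None:
            cfg["encoder_repeats"] = list(cfg["encoder_repeats"])
        sidecar.write_text(json.dumps(cfg, indent=2))
        return path

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        path = Path(path)
        cfg = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if cfg.get("encoder_repeats") is not None:
            cfg["encoder_repeats"] = tuple(cfg["encoder_repeats"])
        config = ModelConfig(**cfg)
        model = build_model(config)
        data = np.load(path)
        for i, p in enumerate(model.net.parameters()):
            p.data = data[f"param_{i:04d}"].astype(np.float32)
        for i, b in enumerate(model.net.buffers()):
            b[...] = data[f"buffer_{i:04d}"]
        return model


def build_unet(config: ModelConfig) -> SegmentationModel:
    if config.architecture != "unet":
        raise ValueError("config.architecture must be 'unet'")
    return SegmentationModel(UNet(config), config)


def build_efficientnetv2s_encoder(
    config: ModelConfig, spec: EncoderSpec | None = None
) -> tuple[EfficientNetV2SEncoder, list[int]]:
    """Build the backbone; returns (encoder, tap channel widths)."""
    if config.input_size % 32:
        raise ValueError("input_size must be divisible by 32")
    enc = EfficientNetV2SEncoder(config, spec)
    return enc, enc.tap_channels


def build_efficientunet(config: ModelConfig, spec: EncoderSpec | None = None) -> SegmentationModel:
    if config.architecture != "efficientunet":
        raise ValueError("config.architecture must be 'efficientunet'")
    return SegmentationModel(EfficientUNet(config, spec), config)


def build_model(config: ModelConfig) -> SegmentationModel:
    if config.architecture == "unet":
        return build_unet(config)
    return build_efficientunet(config)
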