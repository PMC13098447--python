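"""Downsized U-Net collagen segmentation: configs, training, prediction, Dice.

Two reference architectures are provided: U-Net Tiny (filters [8, 16, 32],
32,665 trainable parameters) and U-Net Mini ([32, 64, 128], 517,729).
Both are depth-3 encoders/decoders with two stacked 3x3 conv+ReLU blocks
per level, 2x2 max pooling, bilinear 2x unpooling followed by a
channel-halving convolution, skip concatenation and a 1x1 sigmoid head.
Training uses binary cross-entropy with Adam.

Tiles with less than 5% annotated collagen are discarded from training
and validation pools (never at inference) to stabilize optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .imaging_io import BinaryMask, ProbabilityMap, RasterImage
from .nn import Adam, UNet, bce_with_logits, sigmoid

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "TrainedModel",
    "UNET_TINY",
    "UNET_MINI",
    "build_unet",
    "count_parameters",
    "filter_training_tiles",
    "train_model",
    "predict",
    "dice_score",
    "save_checkpoint",
    "load_checkpoint",
]

MIN_COLLAGEN_FRACTION = 0.05  # "less than 5%" training-tile filter


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 3
    filters: tuple[int, ...] = (8, 16, 32)
    stacked_down: int = 2
    stacked_up: int = 2
    kernel: int = 3
    upsample: str = "bilinear"
    pooling: str = "max"
    final_activation: str = "sigmoid"
    attention: bool = False

    def __post_init__(self) -> None:
        if len(self.filters) != self.depth:
            raise ValueError("len(filters) must equal depth")
        if any(f < 1 for f in self.filters) or self.stacked_down < 1 or self.stacked_up < 1:
            raise ValueError("all layer counts must be >= 1")


UNET_TINY = UNetConfig(filters=(8, 16, 32))
UNET_MINI = UNetConfig(filters=(32, 64, 128))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    loss: str = "bce"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainedModel:
    config: UNetConfig
    parameter_count: int
    network: UNet
    seed: int
    training_log: list[float] = field(default_factory=list)  # per-epoch mean loss


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Instantiate the network described by ``config`` with seeded initialization."""
    if config.upsample != "bilinear" or config.pooling != "max" or config.final_activation != "sigmoid":
        raise ValueError("only bilinear upsampling, max pooling and a sigmoid head are supported")
    return UNet(
        depth=config.depth,
        filters=config.filters,
        stacked_down=config.stacked_down,
        stacked_up=config.stacked_up,
        attention=config.attention,
        seed=seed,
    )


def _count_from_config(config: UNetConfig) -> int:
    """Closed-form parameter count: sum of k^2*cin*cout + cout over all convolutions."""
    k2 = config.kernel**2
    total = 0
    cin = 3
    for i, f in enumerate(config.filters):
        for s in range(config.stacked_down):
            c_in = cin if s == 0 else f
            total += k2 * c_in * f + f
        cin = f
    for i in range(config.depth - 2, -1, -1):
        f, f_up = config.filters[i], config.filters[i + 1]
        total += k2 * f_up * f + f  # channel-halving conv after bilinear upsample
        if config.attention:
            inter = max(f // 2, 1)
            total += (f * inter + inter) * 2 + inter * 1 + 1
        for s in range(config.stacked_up):
            c_in = 2 * f if s == 0 else f
            total += k2 * c_in * f + f
    total += config.filters[0] * 1 + 1  # 1x1 head
    return total


def count_parameters(model_or_config: UNet | UNetConfig | TrainedModel) -> int:
    """Total trainable scalars (weights + biases)."""
    if isinstance(model_or_config, TrainedModel):
        return model_or_config.network.count_parameters()
    if isinstance(model_or_config, UNet):
        return model_or_config.count_parameters()
    return _count_from_config(model_or_config)


def filter_training_tiles(
    tiles: Sequence[tuple[RasterImage, BinaryMask]]
) -> list[tuple[RasterImage, BinaryMask]]:
    """Keep tiles whose mask covers at least 5% of the area (train/val only)."""
    return [(img, m) for img, m in tiles if m.pixels.mean() >= MIN_COLLAGEN_FRACTION]


def _to_batch(images: Sequence[RasterImage]) -> np.ndarray:
    return np.stack([im.pixels for im in images]).astype(np.float32) / 255.0


def train_model(
    config: UNetConfig,
    train: TrainConfig,
    dataset: Sequence[tuple[RasterImage, BinaryMask]],
    apply_filter: bool = True,
) -> TrainedModel:
    """Train a single network on (image, mask) tiles; deterministic given the seed."""
    tiles = filter_training_tiles(dataset) if apply_filter else list(dataset)
    if not tiles:
        raise ValueError("dataset is empty after the 5% collagen filter")
    shapes = {t[0].pixels.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"all tiles must have equal size, got {shapes}")

    net = build_unet(config, seed=train.seed)
    opt = Adam(net.parameters(), lr=train.learning_rate)
    x = _to_batch([t[0] for t in tiles])
    y = np.stack([t[1].pixels for t in tiles]).astype(np.float32)[..., None]
    n = len(tiles)
    rng = np.random.default_rng(np.random.SeedSequence([int(train.seed), 23]))
    log: list[float] = []
    for _epoch in range(train.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train.batch_size):
            idx = order[start : start + train.batch_size]
            z = net.forward(x[idx])
            loss, dz = bce_with_logits(z, y[idx])
            net.backward(dz)
            opt.step()
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return TrainedModel(
        config=config,
        parameter_count=net.count_parameters(),
        network=net,
        seed=train.seed,
        training_log=log,
    )


def predict(model: TrainedModel | UNet, image: RasterImage) -> ProbabilityMap:
    """Per-pixel collagen likelihood for one tile."""
    net = model.network if isinstance(model, TrainedModel) else model
    h, w = image.height, image.width
    div = 2 ** (net.depth - 1)
    if h % div or w % div:
        raise ValueError(
            f"tile size {h}x{w} is not divisible by {div}; pad the tile to a multiple of {div}"
        )
    x = image.pixels.astype(np.float32)[None] / 255.0
    probs = sigmoid(net.forward(x))[0, :, :, 0]
    return ProbabilityMap(probs.astype(np.float64))


def dice_score(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice overlap ``2|A ^ B| / (|A| + |B|)``; 1.0 when both masks are empty."""
    if pred.pixels.shape != truth.pixels.shape:
        raise ValueError("mask shapes do not match")
    a, b = pred.pixels, truth.pixels
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


# -- checkpointing -------------------------------------------------------


def save_checkpoint(model: TrainedModel, directory: str | Path, name: str = "model") -> Path:
    """Serialized weights (.npz) plus a JSON sidecar with config, seed and log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(directory / f"{name}.npz", **model.network.state_dict())
    sidecar = {
        "config": asdict(model.config),
        "seed": model.seed,
        "parameter_count": model.parameter_count,
        "training_log": model.training_log,
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
    return directory / f"{name}.npz"


def load_checkpoint(directory: str | Path, name: str = "model") -> TrainedModel:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}.json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["filters"] = tuple(cfg_dict["filters"])
    config = UNetConfig(**cfg_dict)
    net = build_unet(config, seed=sidecar["seed"])
    with np.load(directory / f"{name}.npz") as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return TrainedModel(
        config=config,
        parameter_count=sidecar["parameter_count"],
        network=net,
        seed=sidecar["seed"],
        training_log=list(sidecar["training_log"]),
    )
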