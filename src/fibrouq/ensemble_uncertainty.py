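"""Deep-ensemble prediction and per-pixel uncertainty decomposition.

An ensemble of M independently initialized and trained U-Nets yields
member likelihood maps ``p_m`` and their mean ``p_hat``.  The predictive
variance of the Bernoulli output decomposes per pixel into

    aleatoric = (1/M) sum_m p_m (1 - p_m)
    epistemic = (1/M) sum_m (p_m - p_hat)^2

whose sum is algebraically identical to ``p_hat (1 - p_hat)``.  Aleatoric
uncertainty captures image-intrinsic ambiguity (it concentrates on fiber
boundaries); epistemic uncertainty captures model disagreement and rises
on out-of-distribution inputs such as unseen stain colors or air-bubble
artifacts, which makes its tile mean a practical reliability flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging_io import ProbabilityMap, RasterImage
from .segmentation import (
    TrainConfig,
    TrainedModel,
    UNetConfig,
    load_checkpoint,
    predict,
    save_checkpoint,
    train_model,
)

__all__ = [
    "Ensemble",
    "EnsemblePrediction",
    "UncertaintyMaps",
    "TileUncertaintySummary",
    "DEFAULT_EPISTEMIC_THRESHOLD",
    "derive_member_seed",
    "train_ensemble",
    "ensemble_predict",
    "aleatoric_map",
    "epistemic_map",
    "combined_map",
    "summarize_tile",
    "flag_unreliable",
    "save_ensemble",
    "load_ensemble",
]

#: Typical tile-mean epistemic uncertainty of a well-trained ensemble on
#: in-distribution data; tiles above it deserve review.  Data-dependent.
DEFAULT_EPISTEMIC_THRESHOLD = 0.002


@dataclass
class Ensemble:
    members: list[TrainedModel]
    member_seeds: list[int]
    config: UNetConfig
    train_config: TrainConfig | None = None

    def __post_init__(self) -> None:
        if len(set(self.member_seeds)) != len(self.member_seeds):
            raise ValueError("member seeds must be pairwise distinct")

    @property
    def M(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnsemblePrediction:
    member_maps: tuple[ProbabilityMap, ...]  # p_m, in member order
    mean_map: ProbabilityMap  # p_hat

    @property
    def M(self) -> int:
        return len(self.member_maps)


@dataclass(frozen=True)
class UncertaintyMaps:
    aleatoric: np.ndarray
    epistemic: np.ndarray
    combined: np.ndarray  # = aleatoric + epistemic = p_hat (1 - p_hat)


@dataclass(frozen=True)
class TileUncertaintySummary:
    mean_aleatoric: float
    mean_epistemic: float
    mean_combined: float


def derive_member_seed(master_seed: int, index: int) -> int:
    """Deterministic, pairwise-distinct member seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), 1000 + int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def train_ensemble(
    config: UNetConfig,
    train_config: TrainConfig,
    dataset,
    M: int = 10,
    master_seed: int = 0,
    apply_filter: bool = True,
) -> Ensemble:
    """Train M members from scratch, each with its own derived seed.

    Member seeds control both weight initialization and the data shuffling
    order, so members explore independent optimization trajectories.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    members, seeds = [], []
    for m in range(M):
        seed = derive_member_seed(master_seed, m)
        cfg_m = TrainConfig(
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            loss=train_config.loss,
            optimizer=train_config.optimizer,
            learning_rate=train_config.learning_rate,
            seed=seed,
        )
        try:
            members.append(train_model(config, cfg_m, dataset, apply_filter=apply_filter))
        except Exception as exc:
            raise RuntimeError(f"training failed for ensemble member {m} (seed {seed}): {exc}") from exc
        seeds.append(seed)
    return Ensemble(members=members, member_seeds=seeds, config=config, train_config=train_config)


def ensemble_predict(ensemble: Ensemble, image: RasterImage) -> EnsemblePrediction:
    """Member maps in member order plus their arithmetic mean."""
    maps = tuple(predict(m, image) for m in ensemble.members)
    mean = np.mean([p.pixels for p in maps], axis=0)
    return EnsemblePrediction(member_maps=maps, mean_map=ProbabilityMap(mean))


def _stack(pred: EnsemblePrediction) -> np.ndarray:
    return np.stack([p.pixels for p in pred.member_maps])


def aleatoric_map(pred: EnsemblePrediction) -> np.ndarray:
    """(1/M) sum_m p_m (1 - p_m); in [0, 0.25]."""
    p = _stack(pred)
    return np.mean(p * (1.0 - p), axis=0)


def epistemic_map(pred: EnsemblePrediction) -> np.ndarray:
    """(1/M) sum_m (p_m - p_hat)^2; in [0, 0.25], zero iff members agree."""
    p = _stack(pred)
    return np.mean((p - pred.mean_map.pixels) ** 2, axis=0)


def combined_map(pred: EnsemblePrediction) -> UncertaintyMaps:
    """Full decomposition; combined equals p_hat (1 - p_hat) identically."""
    ale = aleatoric_map(pred)
    epi = epistemic_map(pred)
    return UncertaintyMaps(aleatoric=ale, epistemic=epi, combined=ale + epi)


def summarize_tile(maps: UncertaintyMaps) -> TileUncertaintySummary:
    """Spatial means of the three uncertainty maps."""
    return TileUncertaintySummary(
        mean_aleatoric=float(maps.aleatoric.mean()),
        mean_epistemic=float(maps.epistemic.mean()),
        mean_combined=float(maps.combined.mean()),
    )


def flag_unreliable(
    summary: TileUncertaintySummary,
    epistemic_threshold: float = DEFAULT_EPISTEMIC_THRESHOLD,
) -> bool:
    """True when the tile-mean epistemic uncertainty exceeds the threshold."""
    if epistemic_threshold <= 0:
        raise ValueError("threshold must be > 0")
    return summary.mean_epistemic > epistemic_threshold


# -- serialization -------------------------------------------------------


def save_ensemble(ensemble: Ensemble, directory: str | Path) -> None:
    """Member checkpoints plus an ensemble.json with seeds and config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(ensemble.members):
        save_checkpoint(member, directory, name=f"member_{i:02d}")
    meta = {
        "member_seeds": ensemble.member_seeds,
        "M": ensemble.M,
        "config": {
            "depth": ensemble.config.depth,
            "filters": list(ensemble.config.filters),
            "stacked_down": ensemble.config.stacked_down,
            "stacked_up": ensemble.config.stacked_up,
            "attention": ensemble.config.attention,
        },
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))


def load_ensemble(directory: str | Path) -> Ensemble:
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    members = [load_checkpoint(directory, name=f"member_{i:02d}") for i in range(meta["M"])]
    cfg = meta["config"]
    config = UNetConfig(
        depth=cfg["depth"],
        filters=tuple(cfg["filters"]),
        stacked_down=cfg["stacked_down"],
        stacked_up=cfg["stacked_up"],
        attention=cfg.get("attention", False),
    )
    return Ensemble(members=members, member_seeds=list(meta["member_seeds"]), config=config)
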