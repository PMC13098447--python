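"""Tile and slide collagen proportionate area (CPA) with ensemble spread.

Two tile-level measures are computed from an ensemble prediction: the
mean collagen prediction ``P`` (spatial mean of the ensemble mean map)
and the segmented area proportion ``B`` (true-pixel fraction after
thresholding the mean map at ``p >= 0.5``).  Their spread across
ensemble members is reported as the interquartile range of the
per-member tile values (linear-interpolation quantiles, type 7).
Slide CPA aggregates tile values weighted by tissue pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import BinaryMask, ProbabilityMap
from .ensemble_uncertainty import EnsemblePrediction

__all__ = [
    "TileQuantification",
    "SlideQuantification",
    "mean_prediction_P",
    "binarize",
    "segmented_area_B",
    "member_values",
    "iqr",
    "quantify_tile",
    "quantify_slide",
    "correlation",
]


@dataclass(frozen=True)
class TileQuantification:
    P: float  # spatial mean of the ensemble mean map
    B: float  # segmented area fraction of the thresholded mean map
    member_P: tuple[float, ...]
    member_B: tuple[float, ...]
    iqr_P: float | None
    iqr_B: float | None
    tile_id: str = ""


@dataclass(frozen=True)
class SlideQuantification:
    cpa: float  # tissue-weighted mean of tile B
    cpa_pred: float  # tissue-weighted mean of tile P
    table: pd.DataFrame = field(repr=False, default=None)


def mean_prediction_P(mean_map: ProbabilityMap) -> float:
    """Arithmetic mean of the likelihood map over all pixels."""
    if mean_map.pixels.size == 0:
        raise ValueError("empty probability map")
    return float(mean_map.pixels.mean())


def binarize(prob_map: ProbabilityMap, tau: float = 0.5) -> BinaryMask:
    """Pixel is collagen iff its likelihood is at or above ``tau``."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    return BinaryMask(prob_map.pixels >= tau)


def segmented_area_B(mask: BinaryMask) -> float:
    """Fraction of true pixels."""
    if mask.pixels.size == 0:
        raise ValueError("empty mask")
    return float(mask.pixels.mean())


def member_values(
    pred: EnsemblePrediction, tau: float = 0.5
) -> tuple[list[float], list[float]]:
    """Per-member tile means and per-member thresholded area fractions."""
    member_P = [mean_prediction_P(p) for p in pred.member_maps]
    member_B = [segmented_area_B(binarize(p, tau)) for p in pred.member_maps]
    return member_P, member_B


def iqr(values: Sequence[float]) -> float:
    """Q3 - Q1 with linear interpolation between order statistics (type 7)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("iqr requires at least two values")
    q1, q3 = np.percentile(values, [25.0, 75.0], method="linear")
    return float(q3 - q1)


def quantify_tile(
    pred: EnsemblePrediction, tau: float = 0.5, tile_id: str = ""
) -> TileQuantification:
    """Both CPA measures for one tile plus their ensemble IQRs.

    With a single member the point estimates are still produced but the
    IQRs are ``None`` (flagged by absence).
    """
    P = mean_prediction_P(pred.mean_map)
    B = segmented_area_B(binarize(pred.mean_map, tau))
    m_P, m_B = member_values(pred, tau)
    has_spread = pred.M >= 2
    return TileQuantification(
        P=P,
        B=B,
        member_P=tuple(m_P),
        member_B=tuple(m_B),
        iqr_P=iqr(m_P) if has_spread else None,
        iqr_B=iqr(m_B) if has_spread else None,
        tile_id=tile_id,
    )


def quantify_slide(
    tiles: Sequence[TileQuantification], tissue_pixels: Sequence[int]
) -> SlideQuantification:
    """Tissue-pixel-weighted aggregation of tile CPA values."""
    if len(tiles) == 0:
        raise ValueError("quantify_slide requires at least one tile")
    if len(tiles) != len(tissue_pixels):
        raise ValueError("one tissue pixel count per tile is required")
    w = np.asarray(tissue_pixels, dtype=np.float64)
    if w.sum() <= 0:
        raise ValueError("zero total tissue area")
    b = np.asarray([t.B for t in tiles])
    p = np.asarray([t.P for t in tiles])
    table = pd.DataFrame(
        dict(
            tile_id=[t.tile_id for t in tiles],
            P=p,
            B=b,
            iqr_P=[t.iqr_P for t in tiles],
            iqr_B=[t.iqr_B for t in tiles],
            tissue_pixels=w.astype(int),
        )
    )
    return SlideQuantification(
        cpa=float((b * w).sum() / w.sum()),
        cpa_pred=float((p * w).sum() / w.sum()),
        table=table,
    )


def correlation(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.size != ys.size or xs.size < 3:
        raise ValueError("correlation requires equal-length sequences of >= 3 values")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    xc, yc = xs - xs.mean(), ys - ys.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
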