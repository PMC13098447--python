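"""Primary-color characterization of digital slides and stain deconvolution.

The primary color of a slide is the dominant tissue color found by
(1) grayscale conversion, (2) Otsu tissue/background thresholding,
(3) background whitening, and (4) median-cut color quantization over the
tissue pixels.  Primary colors are reported in both sRGB and CIELAB
(D65, 2 degree observer) so cohorts stained under different protocols can
be compared in a perceptually uniform space.

Stain deconvolution inverts Beer-Lambert optical-density mixing,
``OD_c = -log10(I_c / I0)``, through a 3x3 matrix of unit stain vectors
to obtain per-stain concentration maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import color as _skcolor

from .imaging_io import BinaryMask, GrayImage, PyramidInfo, RasterImage, select_downsample_level

__all__ = [
    "PaletteEntry",
    "PrimaryColorResult",
    "StainMatrix",
    "CohortColorRecord",
    "SIRIUS_RED_DEFAULT_STAINS",
    "to_grayscale",
    "otsu_threshold",
    "tissue_mask",
    "whiten_background",
    "median_cut",
    "primary_color",
    "rgb_to_cielab",
    "deconvolve_stains",
    "cohort_color_table",
]


@dataclass(frozen=True)
class PaletteEntry:
    """One bucket of a median-cut palette: representative color and pixel count."""

    rgb: tuple[int, int, int]
    count: int


@dataclass(frozen=True)
class PrimaryColorResult:
    rgb: tuple[int, int, int]
    lab: tuple[float, float, float]
    tissue_fraction: float
    level_used: int = 0


@dataclass(frozen=True)
class StainMatrix:
    """Columns are unit-length optical-density direction vectors (R, G, B OD), one per stain."""

    matrix: np.ndarray  # 3 x 3
    names: tuple[str, str, str] = ("stain_1", "stain_2", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain vectors must have unit norm, got norms {norms}")
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e8:
            raise ValueError("stain matrix is singular or near-singular")
        object.__setattr__(self, "matrix", m)


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


#: Editable default: a Sirius-Red-like red vector, a hematoxylin-like vector,
#: and their orthogonal residual.  Real slides need per-slide estimated vectors.
SIRIUS_RED_DEFAULT_STAINS = StainMatrix(
    np.column_stack(
        [
            _unit([0.10, 0.75, 0.65]),  # Sirius Red: absorbs green/blue
            _unit([0.65, 0.70, 0.29]),  # hematoxylin-like
            _unit(np.cross(_unit([0.10, 0.75, 0.65]), _unit([0.65, 0.70, 0.29]))),
        ]
    ),
    names=("sirius_red", "hematoxylin", "residual"),
)


def to_grayscale(image: RasterImage) -> GrayImage:
    """BT.601 luma: ``round(0.299 R + 0.587 G + 0.114 B)``, clipped to [0, 255]."""
    px = image.pixels.astype(np.float64)
    gray = 0.299 * px[:, :, 0] + 0.587 * px[:, :, 1] + 0.114 * px[:, :, 2]
    return GrayImage(np.clip(np.rint(gray), 0, 255).astype(np.uint8))


def otsu_threshold(image: GrayImage) -> int:
    """Otsu's threshold on the 256-bin histogram.

    Returns the smallest ``t`` maximizing the between-class variance of the
    classes ``{<= t}`` and ``{> t}``.  A constant image has no valid
    threshold and raises ``ValueError``.
    """
    hist = np.bincount(image.pixels.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has a single intensity value")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)  # omega[t] = P(<= t)
    mu = np.cumsum(p * levels)  # first moment up to t
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def tissue_mask(image: GrayImage, t: int) -> BinaryMask:
    """Tissue = pixels at or below the threshold (background is strictly above)."""
    if not 0 <= t <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return BinaryMask(image.pixels <= t)


def whiten_background(image: RasterImage, tissue: BinaryMask) -> RasterImage:
    """Replace background (non-tissue) pixels with white; tissue pixels unchanged."""
    if tissue.pixels.shape != image.pixels.shape[:2]:
        raise ValueError("mask shape does not match image shape")
    out = image.pixels.copy()
    out[~tissue.pixels] = 255
    return RasterImage(out)


def _box_ranges(pixels: np.ndarray) -> np.ndarray:
    return pixels.max(axis=0).astype(np.int64) - pixels.min(axis=0).astype(np.int64)


def median_cut(pixels: Iterable[Sequence[int]], k: int) -> list[PaletteEntry]:
    """Median-cut color quantization.

    Boxes are split iteratively: the box whose largest per-channel range is
    greatest is cut at the median of that channel (the lower half takes
    values <= median), until ``min(k, #distinct colors)`` boxes exist.
    Ties between boxes go to the lowest box index; ties between channels to
    R, then G, then B.  Each entry's color is the rounded per-channel mean
    of its box; entries are sorted by count, descending.
    """
    px = np.asarray(list(pixels) if not isinstance(pixels, np.ndarray) else pixels)
    if px.size == 0:
        raise ValueError("median_cut requires at least one pixel")
    px = px.reshape(-1, 3).astype(np.int64)
    n_distinct = len(np.unique(px, axis=0))
    target = min(int(k), n_distinct)
    if k < 1:
        raise ValueError("k must be >= 1")

    boxes: list[np.ndarray] = [px]
    while len(boxes) < target:
        ranges = [_box_ranges(b) for b in boxes]
        scores = [int(r.max()) for r in ranges]
        best = max(scores)
        if best == 0:  # all boxes uniform; cannot split further
            break
        bi = scores.index(best)  # lowest index among ties
        box = boxes[bi]
        ch = int(np.argmax(ranges[bi]))  # R,G,B order among channel ties
        med = float(np.median(box[:, ch]))
        lower = box[box[:, ch] <= med]
        upper = box[box[:, ch] > med]
        if len(upper) == 0:  # median equals the channel max; cut strictly below
            lower = box[box[:, ch] < med]
            upper = box[box[:, ch] >= med]
        boxes[bi : bi + 1] = [lower, upper]

    entries = [
        PaletteEntry(tuple(int(v) for v in np.rint(b.mean(axis=0))), len(b)) for b in boxes
    ]
    entries.sort(key=lambda e: -e.count)
    return entries


def rgb_to_cielab(rgb: Sequence[float]) -> tuple[float, float, float]:
    """sRGB (8-bit) to CIELAB under D65 / 2 degree observer."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape != (3,) or rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("rgb must be three values in [0, 255]")
    lab = _skcolor.rgb2lab(rgb[None, None, :] / 255.0)[0, 0]
    return (float(lab[0]), float(lab[1]), float(lab[2]))


def primary_color(
    image: RasterImage,
    pyramid: Sequence[RasterImage] | None = None,
    k: int = 3,
    max_side: int = 2048,
    include_background: bool = False,
) -> PrimaryColorResult:
    """Dominant tissue color of a slide image (most-populous median-cut bucket).

    When ``pyramid`` (a list of level images, level 0 = full resolution) is
    given, the analysis runs on the smallest level fitting ``max_side``.
    Ties for the most-populous bucket are broken toward the darker L*.
    By default the quantization runs on tissue pixels only; set
    ``include_background`` to quantize the whitened full image instead.
    """
    level_used = 0
    if pyramid is not None and len(pyramid) > 0:
        info = PyramidInfo(tuple((im.height, im.width) for im in pyramid))
        level_used = select_downsample_level(info, max_side=max_side)
        image = pyramid[level_used]

    gray = to_grayscale(image)
    t = otsu_threshold(gray)
    tissue = tissue_mask(gray, t)
    if not tissue.pixels.any():
        raise ValueError("no tissue detected")
    if include_background:
        source = whiten_background(image, tissue).pixels.reshape(-1, 3)
    else:
        source = image.pixels[tissue.pixels]
    palette = median_cut(source, k=k)
    top_count = palette[0].count
    tied = [e for e in palette if e.count == top_count]
    chosen = min(tied, key=lambda e: rgb_to_cielab(e.rgb)[0])
    return PrimaryColorResult(
        rgb=chosen.rgb,
        lab=rgb_to_cielab(chosen.rgb),
        tissue_fraction=float(tissue.pixels.mean()),
        level_used=level_used,
    )


def deconvolve_stains(
    image: RasterImage, stains: StainMatrix = SIRIUS_RED_DEFAULT_STAINS, I0: float = 255.0
) -> np.ndarray:
    """Per-stain concentration maps from Beer-Lambert optical densities.

    ``OD_c = -log10(max(I_c, 1) / I0)`` per channel; concentrations are
    ``stains^-1 @ OD`` with negatives clamped to zero.  Returns a
    ``3 x H x W`` array ordered as the stain matrix columns.
    """
    od = -np.log10(np.maximum(image.pixels.astype(np.float64), 1.0) / I0)
    inv = np.linalg.inv(stains.matrix)
    conc = np.einsum("sc,hwc->shw", inv, od)
    return np.clip(conc, 0.0, None)


@dataclass(frozen=True)
class CohortColorRecord:
    slide_id: str
    cohort: str
    rgb: tuple[int, int, int] | None
    lab: tuple[float, float, float] | None
    tissue_fraction: float | None = None
    level_used: int | None = None
    error: str | None = None


def cohort_color_table(
    slides: Iterable[tuple[str, str, RasterImage]]
) -> list[CohortColorRecord]:
    """Primary color of every slide, in input order; per-slide failures become error rows."""
    records: list[CohortColorRecord] = []
    for slide_id, cohort, image in slides:
        try:
            res = primary_color(image)
            records.append(
                CohortColorRecord(
                    slide_id, cohort, res.rgb, res.lab, res.tissue_fraction, res.level_used
                )
            )
        except Exception as exc:  # noqa: BLE001 - error rows, not aborts
            records.append(CohortColorRecord(slide_id, cohort, None, None, error=str(exc)))
    if not records:
        raise ValueError("cohort_color_table requires at least one slide")
    return records


def color_table_to_frame(records: Sequence[CohortColorRecord]) -> pd.DataFrame:
    """Tabular view with columns slide_id, cohort, r, g, b, L, a, b_star, ..."""
    rows = []
    for rec in records:
        r, g, b = rec.rgb if rec.rgb is not None else (None, None, None)
        L, a, bs = rec.lab if rec.lab is not None else (None, None, None)
        rows.append(
            dict(
                slide_id=rec.slide_id,
                cohort=rec.cohort,
                r=r,
                g=g,
                b=b,
                L=L,
                a=a,
                b_star=bs,
                tissue_fraction=rec.tissue_fraction,
                level_used=rec.level_used,
                error=rec.error,
            )
        )
    return pd.DataFrame(rows)
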