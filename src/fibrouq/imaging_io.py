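"""Raster image I/O, pyramid level selection, and tile-grid enumeration.

All coordinates in this package are 0-based, half-open, in (row, col)
order.  Images are 8-bit sRGB ``H x W x 3`` arrays; masks are boolean
``H x W`` arrays serialized as single-channel {0, 255} PNGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "RasterImage",
    "GrayImage",
    "BinaryMask",
    "ProbabilityMap",
    "PyramidInfo",
    "read_raster",
    "write_raster",
    "read_mask",
    "write_mask",
    "select_downsample_level",
    "tile_grid",
]

_LOSSLESS_SUFFIXES = {".png", ".tif", ".tiff"}
_READ_SUFFIXES = _LOSSLESS_SUFFIXES | {".jpg", ".jpeg"}


@dataclass(frozen=True)
class RasterImage:
    """8-bit sRGB image tile."""

    pixels: np.ndarray  # H x W x 3, uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """8-bit single-channel image."""

    pixels: np.ndarray  # H x W, uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected H x W array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean mask; semantics (tissue vs background, collagen vs not) depend on role."""

    pixels: np.ndarray  # H x W, bool

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected H x W array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def fraction(self) -> float:
        """Fraction of true pixels."""
        return float(self.pixels.mean())


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel likelihood in [0, 1]."""

    pixels: np.ndarray  # H x W, float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected H x W array, got shape {px.shape}")
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class PyramidInfo:
    """Dimensions of each downsample level of a slide pyramid, level 0 = full resolution."""

    level_dims: tuple = field(default_factory=tuple)  # ((H0, W0), (H1, W1), ...)

    def __post_init__(self) -> None:
        dims = tuple((int(h), int(w)) for h, w in self.level_dims)
        for (h0, w0), (h1, w1) in zip(dims, dims[1:]):
            if not (h1 < h0 and w1 < w0):
                raise ValueError("pyramid level dimensions must strictly decrease")
        object.__setattr__(self, "level_dims", dims)

    def __len__(self) -> int:
        return len(self.level_dims)


def read_raster(path: str | Path) -> RasterImage:
    """Read a PNG, TIFF or JPEG file as an 8-bit sRGB image.

    Grayscale sources are replicated to three channels.
    """
    path = Path(path)
    if path.suffix.lower() not in _READ_SUFFIXES:
        raise IOError(f"unsupported image format: {path}")
    try:
        with Image.open(path) as im:
            im = im.convert("RGB") if im.mode not in ("RGB", "L") else im.copy()
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return RasterImage(arr)


def write_raster(image: RasterImage, path: str | Path) -> None:
    """Write an image to PNG or TIFF (lossless round-trip guaranteed)."""
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS_SUFFIXES:
        raise IOError(
            f"refusing to write analysis output to lossy/unknown format: {path.suffix!r}"
        )
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    Image.fromarray(image.pixels, mode="RGB").save(path)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a single-channel {0, 255} PNG mask; values >= 128 are true."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise IOError(f"cannot read mask file {path}: {exc}") from exc
    return BinaryMask(arr >= 128)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a boolean mask as a single-channel {0, 255} PNG."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L").save(path)


def select_downsample_level(pyramid: PyramidInfo, max_side: int = 2048) -> int:
    """Smallest level index whose longer side fits in ``max_side``.

    Falls back to the last (smallest) level when no level qualifies.
    """
    if len(pyramid) == 0:
        raise ValueError("empty pyramid")
    for i, (h, w) in enumerate(pyramid.level_dims):
        if max(h, w) <= max_side:
            return i
    return len(pyramid) - 1


def tile_grid(
    height: int, width: int, tile: int = 512, stride: int = 512
) -> list[tuple[int, int, int, int]]:
    """Row-major list of (row0, col0, row1, col1) boxes fully inside the image.

    Boxes are half-open; partial edge tiles are dropped so every box is a
    full ``tile x tile`` crop.
    """
    if tile < 1 or stride < 1:
        raise ValueError("tile and stride must be >= 1")
    boxes = []
    for r0 in range(0, height - tile + 1, stride):
        for c0 in range(0, width - tile + 1, stride):
            boxes.append((r0, c0, r0 + tile, c0 + tile))
    return boxes
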