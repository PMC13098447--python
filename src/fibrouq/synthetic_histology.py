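"""Synthetic PicroSirius-Red-like tiles with ground-truth collagen masks.

The generator emulates what the downstream pipeline must cope with on
real multi-site slides: dark red fractal-like collagen fiber networks on
paler counterstained tissue, per-"site" stain palettes that form
separable color clusters, weak unspecific staining of the parenchyma,
air-bubble artifacts, and JPEG compression noise.

Rendering is physical: per-pixel stain strengths are composed through
Beer-Lambert attenuation ``I = background * 10^(-sum strengths * OD)``,
so stain deconvolution and intensity gradients behave coherently.  Every
operation is a pure function of its spec and an integer seed.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology as skmorph

from .imaging_io import BinaryMask, RasterImage

__all__ = [
    "StainPalette",
    "FiberSpec",
    "ArtifactSpec",
    "SyntheticTile",
    "DEFAULT_PALETTES",
    "OOD_PALETTE",
    "generate_fiber_mask",
    "render_tile",
    "add_air_bubble",
    "add_jpeg_noise",
    "make_cohort",
    "FiberGenerationError",
]


class FiberGenerationError(RuntimeError):
    """Raised when the target collagen fraction cannot be reached."""


def _unit(v: Sequence[float]) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=np.float64)
    a = a / np.linalg.norm(a)
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class StainPalette:
    """Optical-density description of one site's staining protocol."""

    palette_id: str
    collagen_od: tuple[float, float, float]  # unit OD direction of the collagen dye
    collagen_strength: tuple[float, float] = (0.8, 1.6)
    counterstain_od: tuple[float, float, float] | None = None
    counterstain_strength: tuple[float, float] = (0.05, 0.20)
    background_rgb: tuple[int, int, int] = (248, 248, 246)
    intensity_jitter: float = 0.01  # multiplicative noise SD
    unspecific_fraction: float = 0.15  # fraction of collagen OD leaking into parenchyma

    def __post_init__(self) -> None:
        if any(c < 240 for c in self.background_rgb):
            raise ValueError("background must be near-white (channels >= 240)")
        if min(self.collagen_strength) < 0 or min(self.counterstain_strength) < 0:
            raise ValueError("OD strengths must be >= 0")
        object.__setattr__(self, "collagen_od", _unit(self.collagen_od))
        if self.counterstain_od is not None:
            object.__setattr__(self, "counterstain_od", _unit(self.counterstain_od))


#: Two training "sites": classic PSR (red collagen, pale picric-yellow tissue)
#: and PSR with a green cytoplasm counterstain and a slightly different red.
DEFAULT_PALETTES = (
    StainPalette(
        "site_red_yellow",
        collagen_od=(0.10, 0.75, 0.65),
        counterstain_od=(0.02, 0.12, 0.55),  # pale yellow (absorbs blue)
        counterstain_strength=(0.08, 0.22),
    ),
    StainPalette(
        "site_red_green",
        collagen_od=(0.22, 0.72, 0.62),
        counterstain_od=(0.60, 0.12, 0.60),  # green cytoplasm stain (absorbs red/blue)
        counterstain_strength=(0.10, 0.25),
    ),
)

#: Held-out "unseen site" used for out-of-distribution experiments:
#: blue-gray collagen with a purple nuclear counterstain, far from both
#: training palettes in CIELAB.
OOD_PALETTE = StainPalette(
    "site_blue_purple",
    collagen_od=(0.72, 0.55, 0.18),
    counterstain_od=(0.35, 0.65, 0.25),
    counterstain_strength=(0.12, 0.30),
)


@dataclass(frozen=True)
class FiberSpec:
    """Morphology of the synthetic collagen fiber network."""

    n_fibers: tuple[int, int] = (3, 14)
    thickness: tuple[int, int] = (1, 5)  # px
    waviness: float = 0.35  # SD of per-step direction change (radians)
    branch_prob: float = 0.08  # per-segment branching probability
    target_fraction: tuple[float, float] = (0.06, 0.30)

    def __post_init__(self) -> None:
        if self.thickness[0] < 1:
            raise ValueError("thickness must be >= 1 px")
        lo, hi = self.target_fraction
        if not (0 <= lo <= hi < 1):
            raise ValueError("target_fraction must be an increasing range in [0, 1)")


@dataclass(frozen=True)
class ArtifactSpec:
    """Optional tile artifacts: an air bubble and/or JPEG recompression."""

    bubble_center: tuple[int, int] | None = None  # (row, col)
    bubble_radius: int = 0
    bubble_ring_width: int | None = None  # default: radius // 6, at least 3 px
    jpeg_quality: int | None = None


@dataclass(frozen=True)
class SyntheticTile:
    image: RasterImage
    mask: BinaryMask
    collagen_fraction: float
    palette_id: str
    artifact_flags: frozenset = field(default_factory=frozenset)
    seed: int = 0
    tile_id: str = ""
    split: str = ""


def _tile_seed(master_seed: int, index: int, stream: str) -> int:
    """Stable per-tile substream below 2**31, order-independent across tiles.

    The stream label is mixed in via CRC32 (process-independent, unlike
    Python's salted ``hash``) so regeneration is bit-identical everywhere.
    """
    label = zlib.crc32(stream.encode()) % (2**31)
    ss = np.random.SeedSequence([int(master_seed), int(index), label])
    return int(ss.generate_state(1)[0] % (2**31))


def _draw_fiber(size: int, rng: np.random.Generator, spec: FiberSpec) -> np.ndarray:
    """One wavy, possibly branching fiber: dilated random-walk strands.

    A shared step budget bounds the total length across all branches, so
    the branching process always terminates.
    """
    t_lo, t_hi = spec.thickness
    out = np.zeros((size, size), dtype=bool)
    stack = [(rng.uniform(0, size), rng.uniform(0, size), rng.uniform(0, 2 * np.pi))]
    budget = int(size * 2.5)
    step = 3.0
    while stack and budget > 0:
        r, c, ang = stack.pop()
        thickness = int(rng.integers(t_lo, t_hi + 1))
        canvas = np.zeros((size, size), dtype=bool)
        n_steps = int(rng.integers(max(size // 4, 8), max(size, 9)))
        for _ in range(n_steps):
            if budget <= 0:
                break
            budget -= 1
            ang += rng.normal(0.0, spec.waviness)
            r2, c2 = r + step * np.sin(ang), c + step * np.cos(ang)
            rr, cc = skdraw.line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            canvas[rr[keep], cc[keep]] = True
            r, c = r2, c2
            if not (-size * 0.5 < r < size * 1.5 and -size * 0.5 < c < size * 1.5):
                break
            if rng.random() < spec.branch_prob:
                stack.append((r, c, ang + rng.normal(0.0, 3 * spec.waviness) + rng.choice((-0.9, 0.9))))
        if thickness > 1:
            canvas = ndi.binary_dilation(canvas, structure=skmorph.disk(thickness // 2))
        out |= canvas
    return out


def generate_fiber_mask(spec: FiberSpec, size: int, seed: int, max_attempts: int = 20) -> BinaryMask:
    """Ground-truth collagen mask: union of dilated wavy branching strands.

    Fibers are added until the collagen fraction enters
    ``spec.target_fraction``; overshooting restarts with a fresh substream,
    up to ``max_attempts`` attempts.  Deterministic given ``(spec, size, seed)``.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    lo, hi = spec.target_fraction
    n_lo, n_hi = spec.n_fibers
    if n_hi == 0:
        if lo > 0:
            raise FiberGenerationError("n_fibers = 0 cannot reach a positive target fraction (achieved 0.0)")
        return BinaryMask(np.zeros((size, size), dtype=bool))

    best = 0.0
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        mask = np.zeros((size, size), dtype=bool)
        n = 0
        while n < n_hi:
            mask = mask | _draw_fiber(size, rng, spec)
            n += 1
            frac = mask.mean()
            if frac > hi:
                break
            if frac >= lo and n >= n_lo:
                return BinaryMask(mask)
        best = max(best, float(mask.mean()))
    raise FiberGenerationError(
        f"could not reach target fraction {spec.target_fraction} in {max_attempts} attempts "
        f"(best achieved fraction {best:.4f})"
    )


def _smooth_field(size: int, rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Smooth random field rescaled to [0, 1]."""
    f = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.full_like(f, 0.5)


def render_tile(mask: BinaryMask, palette: StainPalette, seed: int) -> RasterImage:
    """Render a collagen mask into an 8-bit sRGB tile under one stain palette.

    Collagen pixels carry the collagen dye at a strength modulated by a
    smooth local thickness field; the rest of the tissue carries the
    counterstain plus a small unspecific fraction of the collagen dye
    (parenchyma staining).  Multiplicative intensity jitter is applied last.
    """
    size = mask.pixels.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    s_lo, s_hi = palette.collagen_strength
    thickness_field = _smooth_field(size, rng, sigma=size / 10.0)
    coll_strength = s_lo + thickness_field * (s_hi - s_lo)

    od = np.zeros((size, size, 3), dtype=np.float64)
    coll_vec = np.asarray(palette.collagen_od)
    od += (coll_strength * mask.pixels)[:, :, None] * coll_vec
    tissue = ~mask.pixels
    if palette.counterstain_od is not None:
        c_lo, c_hi = palette.counterstain_strength
        cs_field = _smooth_field(size, rng, sigma=size / 6.0)
        cs_strength = c_lo + cs_field * (c_hi - c_lo)
        od += (cs_strength * tissue)[:, :, None] * np.asarray(palette.counterstain_od)
    od += (palette.unspecific_fraction * coll_strength * tissue)[:, :, None] * coll_vec

    bg = np.asarray(palette.background_rgb, dtype=np.float64)
    img = bg * np.power(10.0, -od)
    img *= 1.0 + palette.intensity_jitter * rng.standard_normal((size, size, 1))
    return RasterImage(np.clip(np.rint(img), 0, 255).astype(np.uint8))


def add_air_bubble(
    image: RasterImage, spec: ArtifactSpec, seed: int
) -> tuple[RasterImage, BinaryMask]:
    """Brighten a disc toward white with a darker refractive ring at its edge.

    Returns the modified image and the artifact region (ring + interior).
    The ground-truth collagen mask of the tile is never touched.
    """
    h, w = image.height, image.width
    if spec.bubble_radius == 0:
        return image, BinaryMask(np.zeros((h, w), dtype=bool))
    if spec.bubble_center is None:
        raise ValueError("bubble_center required when bubble_radius > 0")
    r0, c0 = spec.bubble_center
    rad = spec.bubble_radius
    if not (rad <= r0 < h - rad and rad <= c0 < w - rad):
        raise ValueError("bubble does not fit inside the tile")
    ring_width = spec.bubble_ring_width if spec.bubble_ring_width is not None else max(rad // 6, 3)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    out = image.pixels.astype(np.float64)
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    interior = dist <= max(rad - ring_width, 0)
    ring = (dist <= rad) & ~interior
    alpha = 0.85 + 0.05 * rng.random()
    out[interior] = (1 - alpha) * out[interior] + alpha * 255.0
    out[ring] *= 0.55
    region = BinaryMask(dist <= rad)
    return RasterImage(np.clip(np.rint(out), 0, 255).astype(np.uint8)), region


def add_jpeg_noise(image: RasterImage, quality: int) -> RasterImage:
    """Encode-decode through JPEG at the given quality (1-100); dimensions preserved."""
    if not 1 <= quality <= 100:
        raise ValueError("quality must lie in [1, 100]")
    buf = io.BytesIO()
    kwargs = {"subsampling": 0} if quality >= 95 else {}  # high quality: no chroma subsampling
    Image.fromarray(image.pixels, mode="RGB").save(buf, format="JPEG", quality=quality, **kwargs)
    buf.seek(0)
    return RasterImage(np.asarray(Image.open(buf).convert("RGB"), dtype=np.uint8))


def make_cohort(
    palettes: Sequence[StainPalette],
    fiber: FiberSpec,
    n_tiles: int,
    artifact_rate: float = 0.0,
    seed: int = 0,
    size: int = 512,
    val_fraction: float = 0.2,
) -> tuple[list[SyntheticTile], dict[str, str]]:
    """Generate a cohort of tiles round-robined over the palettes.

    Each tile draws its fiber mask and rendering from substreams of
    ``(seed, tile index)``, so the cohort is identical regardless of
    generation order.  Returns the tiles and a deterministic train/val
    split (seeded shuffle, ``val_fraction`` held out).
    """
    if n_tiles < 2:
        raise ValueError("n_tiles must be >= 2")
    tiles: list[SyntheticTile] = []
    art_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    for i in range(n_tiles):
        palette = palettes[i % len(palettes)]
        fiber_seed = _tile_seed(seed, i, "fiber")
        render_seed = _tile_seed(seed, i, "render")
        mask = generate_fiber_mask(fiber, size, fiber_seed)
        image = render_tile(mask, palette, render_seed)
        flags = set()
        if art_rng.random() < artifact_rate:
            rad = size // 3  # air bubbles dominate the tiles they afflict
            r0 = int(art_rng.integers(rad, size - rad))
            c0 = int(art_rng.integers(rad, size - rad))
            image, _ = add_air_bubble(
                image,
                ArtifactSpec(bubble_center=(r0, c0), bubble_radius=rad),
                _tile_seed(seed, i, "bubble"),
            )
            flags.add("air_bubble")
        tiles.append(
            SyntheticTile(
                image=image,
                mask=mask,
                collagen_fraction=float(mask.pixels.mean()),
                palette_id=palette.palette_id,
                artifact_flags=frozenset(flags),
                seed=fiber_seed,
                tile_id=f"tile_{i:04d}",
            )
        )
    order = np.random.default_rng(np.random.SeedSequence([int(seed), 17])).permutation(n_tiles)
    n_val = int(round(val_fraction * n_tiles))
    val_ids = {tiles[j].tile_id for j in order[:n_val]}
    split = {t.tile_id: ("val" if t.tile_id in val_ids else "train") for t in tiles}
    tiles = [replace(t, split=split[t.tile_id]) for t in tiles]
    return tiles, split
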