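"""Section image ingestion, downscaling, tissue masking and tiling.

The scoring pipeline operates on whole-section RGB rasters of stained lung
tissue.  Before classification, a section is downscaled by 50% and split
into 512x512-pixel tiles; each tile is later assigned an ordinal fibrosis
grade.  This module implements that fixed geometry plus a simple
luminance/saturation tissue mask used to flag glass-only tiles.

Coordinate convention: 0-based, half-open pixel intervals, (row, col) =
(y, x), row-major tile order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.transform import resize

#: Stains handled by the pipeline; "synthetic" marks procedurally generated fixtures.
KNOWN_STAINS = ("MT", "PSR", "IHC-Col1a1", "IHC-Col3", "IHC-aSMA", "IHC-Gal3", "synthetic")

#: Pixel value used for background padding of partial edge tiles.
BACKGROUND_WHITE = 255

DEFAULT_DOWNSCALE = 0.5
DEFAULT_TILE_SIZE = 512
DEFAULT_MIN_TISSUE_FRACTION = 0.05
DEFAULT_LUMINANCE_THRESHOLD = 0.92
DEFAULT_SATURATION_THRESHOLD = 0.08


@dataclass
class SectionImage:
    """An RGB whole-section raster with optional pixel-size metadata.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    mpp
        Microns per pixel of the raster, if known (> 0).
    stain
        One of :data:`KNOWN_STAINS`.
    ident
        Sample identifier.
    """

    pixels: np.ndarray
    mpp: Optional[float] = None
    stain: str = "synthetic"
    ident: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("section must be at least 1x1 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.mpp is not None and not self.mpp > 0:
            raise ValueError("mpp must be positive")
        if self.stain not in KNOWN_STAINS:
            raise ValueError(f"unknown stain {self.stain!r}; expected one of {KNOWN_STAINS}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TissueMask:
    """Binary tissue/background mask congruent with a section raster."""

    mask: np.ndarray
    luminance_threshold: float = DEFAULT_LUMINANCE_THRESHOLD
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class Tile:
    """One 512x512 (by default) classification unit cut from a section.

    Edge tiles extending past the section bounds are padded with background
    white; ``valid_fraction`` records the in-bounds share of the footprint.
    """

    row_index: int
    col_index: int
    y0: int
    x0: int
    pixels: np.ndarray
    valid_fraction: float
    tissue_fraction: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.valid_fraction <= 1.0):
            raise ValueError("valid_fraction must lie in (0, 1]")
        if not (0.0 <= self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must lie in [0, 1]")


@dataclass
class TileGrid:
    """Row-major grid of tiles covering a (downscaled) section exactly."""

    tiles: list  # list[Tile]
    n_rows: int
    n_cols: int
    tile_size: int
    section_height: int
    section_width: int
    ident: str = ""

    def __iter__(self):
        return iter(self.tiles)

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def excluded_mask(self) -> np.ndarray:
        m = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for t in self.tiles:
            m[t.row_index, t.col_index] = t.excluded
        return m

    def reassemble(self) -> np.ndarray:
        """Stitch valid tile regions back into the section raster (bit-exact)."""
        out = np.empty((self.section_height, self.section_width, 3), dtype=np.uint8)
        for t in self.tiles:
            vh = min(self.tile_size, self.section_height - t.y0)
            vw = min(self.tile_size, self.section_width - t.x0)
            out[t.y0 : t.y0 + vh, t.x0 : t.x0 + vw] = t.pixels[:vh, :vw]
        return out


def load_section(
    path, stain: str = "synthetic", mpp: Optional[float] = None, ident: Optional[str] = None
) -> SectionImage:
    """Read a TIFF or PNG raster into a :class:`SectionImage`.

    Grayscale rasters are replicated to three channels; an alpha channel,
    if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps decoder failures variously
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized raster: {path}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    return SectionImage(pixels=arr, mpp=mpp, stain=stain, ident=ident or path.stem)


def save_raster(path, pixels: np.ndarray) -> None:
    """Write an RGB raster as PNG."""
    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def downscale(section: SectionImage, factor: float = DEFAULT_DOWNSCALE) -> SectionImage:
    """Downscale a section by ``factor`` (default 50%) with area averaging.

    Output dimensions are ``round(dim * factor)`` per axis (half away from
    zero), at least 1.  ``mpp`` grows by ``1/factor`` since pixels get
    coarser.  ``factor = 1`` is a pixel-identical no-op.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"downscale factor must lie in (0, 1], got {factor}")
    if factor == 1.0:
        return SectionImage(
            pixels=section.pixels.copy(), mpp=section.mpp, stain=section.stain, ident=section.ident
        )
    h = max(1, _round_half_away(section.height * factor))
    w = max(1, _round_half_away(section.width * factor))
    out = resize(
        section.pixels.astype(np.float64),
        (h, w, 3),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
        mode="reflect",
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    mpp = section.mpp / factor if section.mpp is not None else None
    return SectionImage(pixels=out, mpp=mpp, stain=section.stain, ident=section.ident)


def tissue_mask(
    section: SectionImage,
    luminance_threshold: float = DEFAULT_LUMINANCE_THRESHOLD,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> TissueMask:
    """Classify pixels as tissue vs glass background.

    A pixel is tissue iff its luminance is below ``luminance_threshold``
    (fraction of full scale) or its saturation exceeds
    ``saturation_threshold`` — white glass is bright and unsaturated,
    stained tissue is darker and/or colored.  Deterministic and idempotent
    in its parameters.
    """
    rgb = section.pixels.astype(np.float64) / 255.0
    lum = rgb2gray(rgb)
    sat = rgb2hsv(rgb)[:, :, 1]
    mask = (lum < luminance_threshold) | (sat > saturation_threshold)
    return TissueMask(
        mask=mask,
        luminance_threshold=luminance_threshold,
        saturation_threshold=saturation_threshold,
    )


def tile_section(
    section: SectionImage,
    tile_size: int = DEFAULT_TILE_SIZE,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
    mask: Optional[TissueMask] = None,
) -> TileGrid:
    """Split an (already downscaled) section into a row-major tile grid.

    The grid has ``ceil(H/tile_size) x ceil(W/tile_size)`` positions and
    partitions the raster exactly.  Edge tiles are padded with background
    white and record their in-bounds ``valid_fraction``.  Tiles whose
    tissue fraction falls below ``min_tissue_fraction`` are flagged
    ``excluded`` (kept in the grid so heatmaps stay congruent with the
    section, but never counted in the composite score).
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if mask is None:
        mask = tissue_mask(section)
    if mask.mask.shape != (section.height, section.width):
        raise ValueError("tissue mask is not congruent with the section")

    n_rows = math.ceil(section.height / tile_size)
    n_cols = math.ceil(section.width / tile_size)
    area = tile_size * tile_size
    tiles: list[Tile] = []
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile_size, c * tile_size
            vh = min(tile_size, section.height - y0)
            vw = min(tile_size, section.width - x0)
            px = np.full((tile_size, tile_size, 3), BACKGROUND_WHITE, dtype=np.uint8)
            px[:vh, :vw] = section.pixels[y0 : y0 + vh, x0 : x0 + vw]
            tissue_frac = float(mask.mask[y0 : y0 + vh, x0 : x0 + vw].sum()) / area
            tiles.append(
                Tile(
                    row_index=r,
                    col_index=c,
                    y0=y0,
                    x0=x0,
                    pixels=px,
                    valid_fraction=(vh * vw) / area,
                    tissue_fraction=tissue_frac,
                    excluded=tissue_frac < min_tissue_fraction,
                )
            )
    return TileGrid(
        tiles=tiles,
        n_rows=n_rows,
        n_cols=n_cols,
        tile_size=tile_size,
        section_height=section.height,
        section_width=section.width,
        ident=section.ident,
    )


def write_tile_manifest(grid: TileGrid, path) -> None:
    """Write the tile manifest TSV (one row per grid tile)."""
    import pandas as pd

    rows = [
        dict(
            ident=grid.ident,
            row=t.row_index,
            col=t.col_index,
            y0=t.y0,
            x0=t.x0,
            tile_size=grid.tile_size,
            valid_fraction=t.valid_fraction,
            tissue_fraction=t.tissue_fraction,
            excluded=int(t.excluded),
        )
        for t in grid.tiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
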