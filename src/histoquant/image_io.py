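"""Section-image containers, bit-depth/gamma normalization, and tile stitching.

Whole-section fluorescence images are acquired as a rectangular grid of
overlapping (or abutting) camera fields that must be assembled into one
mosaic before segmentation.  Acquisition is typically 12-bit; downstream
processing standardizes to 8-bit with an optional gamma correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "SectionImage",
    "TileGrid",
    "convert_bit_depth",
    "gamma_correct",
    "stitch",
    "read_tiff",
    "write_tiff",
    "tile_filename",
]

_VALID_BIT_DEPTHS = (8, 12, 16)


@dataclass
class SectionImage:
    """One channel's pixel raster plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D grayscale or (H, W, 3) RGB array of unsigned integers.
    bit_depth
        Declared bit depth; pixel values must fit in ``[0, 2**bit_depth)``.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    channel
        Stain/channel label, e.g. ``"DAPI"``, ``"Iba1"``, ``"ED1"``, ``"HES"``.
    meta
        Provenance: animal id, treatment group, bregma level (mm),
        technical-replicate index.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float = 0.65
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}, got {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.pixels.size and int(self.pixels.max()) >= 2**self.bit_depth:
            raise ValueError(
                f"pixel values exceed declared {self.bit_depth}-bit range "
                f"(max={int(self.pixels.max())})"
            )

    @property
    def vmax(self) -> int:
        """Largest representable grey level at the declared bit depth."""
        return 2**self.bit_depth - 1

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass
class TileGrid:
    """Acquisition grid of tiles indexed ``(col, row)``, col-major origin top-left.

    ``tiles[(col, row)]`` may be missing (None / absent key) only as an error
    condition; :func:`stitch` rejects incomplete grids.
    """

    tiles: dict
    grid_w: int
    grid_h: int
    overlap_px: int = 0

    def __post_init__(self) -> None:
        if self.grid_w < 1 or self.grid_h < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.overlap_px < 0:
            raise ValueError("overlap_px must be non-negative")


def convert_bit_depth(img: SectionImage, target: int = 8) -> SectionImage:
    """Linearly map a 12- or 16-bit image onto the full 8-bit range.

    The map is ``v -> floor(v * 255 / (2**bit_depth - 1))``: full-range and
    image-independent (no per-image min-max stretch), so identical grey values
    always convert identically and pixel ordering is preserved.
    """
    if target != 8:
        raise ValueError("only conversion to 8-bit is supported")
    if img.bit_depth == 8:
        warnings.warn("image is already 8-bit; returning it unchanged", stacklevel=2)
        return img
    scaled = (img.pixels.astype(np.uint32) * 255) // img.vmax
    return replace(img, pixels=scaled.astype(np.uint8), bit_depth=8)


def gamma_correct(img: SectionImage, gamma: float) -> SectionImage:
    """Apply ``v -> round((v / vmax)**gamma * vmax)`` (round half-up).

    Monotone non-decreasing in ``v`` with both endpoints fixed; ``gamma=1``
    is the identity.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if gamma == 1.0:
        return img
    vmax = img.vmax
    normalized = img.pixels.astype(np.float64) / vmax
    out = np.floor(np.power(normalized, gamma) * vmax + 0.5)
    return replace(img, pixels=out.astype(img.pixels.dtype))


def stitch(grid: TileGrid) -> SectionImage:
    """Assemble a complete tile grid into one mosaic.

    Output size is ``grid_w*tile_w - (grid_w-1)*overlap`` by the analogous
    height.  Tiles are pasted in raster order with the later tile overwriting
    the shared overlap band (no blending: counting operates on segmented
    objects, not seam aesthetics).
    """
    missing = [
        (c, r)
        for c in range(grid.grid_w)
        for r in range(grid.grid_h)
        if grid.tiles.get((c, r)) is None
    ]
    if missing:
        raise ValueError(f"incomplete tile grid; missing (col,row) slots: {missing}")

    tiles = [grid.tiles[(c, r)] for c in range(grid.grid_w) for r in range(grid.grid_h)]
    ref = tiles[0]
    th, tw = ref.pixels.shape[:2]
    for t in tiles:
        if t.pixels.shape != ref.pixels.shape:
            raise ValueError("all tiles must share dimensions")
        if t.bit_depth != ref.bit_depth:
            raise ValueError("all tiles must share bit depth")
        if t.channel != ref.channel:
            raise ValueError("all tiles must share channel")

    ov = grid.overlap_px
    if ov >= tw or ov >= th:
        raise ValueError("overlap_px must be smaller than the tile size")
    out_w = grid.grid_w * tw - (grid.grid_w - 1) * ov
    out_h = grid.grid_h * th - (grid.grid_h - 1) * ov
    shape = (out_h, out_w) + ref.pixels.shape[2:]
    mosaic = np.zeros(shape, dtype=ref.pixels.dtype)
    for c in range(grid.grid_w):
        for r in range(grid.grid_h):
            y0 = r * (th - ov)
            x0 = c * (tw - ov)
            mosaic[y0 : y0 + th, x0 : x0 + tw] = grid.tiles[(c, r)].pixels
    return replace(ref, pixels=mosaic, meta=dict(ref.meta))


def tile_filename(section: str, col: int, row: int) -> str:
    """Canonical tile-file naming: ``{section}_{col}_{row}.tif``."""
    return f"{section}_{col}_{row}.tif"


def read_tiff(path, bit_depth: int | None = None, pixel_size_um: float = 0.65,
              channel: str = "", meta: dict | None = None) -> SectionImage:
    """Load a TIFF into a :class:`SectionImage`.

    If ``bit_depth`` is not given it is inferred from the dtype (uint8 -> 8,
    uint16 -> 16); 12-bit data stored in uint16 containers must be declared
    explicitly.
    """
    pixels = tifffile.imread(str(path))
    if bit_depth is None:
        bit_depth = 8 if pixels.dtype == np.uint8 else 16
    return SectionImage(
        pixels=pixels,
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        channel=channel,
        meta=meta or {},
    )


def write_tiff(img: SectionImage, path, as_rgb: bool = False) -> Path:
    """Write a TIFF; ``as_rgb`` replicates an 8-bit grey plane into RGB on save.

    Computation always stays single-channel; RGB is a save-time convention only.
    """
    path = Path(path)
    pixels = img.pixels
    if as_rgb and pixels.ndim == 2:
        if img.bit_depth != 8:
            raise ValueError("RGB save requires an 8-bit image; convert first")
        pixels = np.stack([pixels] * 3, axis=-1)
    if img.bit_depth == 12:
        pixels = pixels.astype(np.uint16)
    tifffile.imwrite(str(path), pixels)
    return path
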