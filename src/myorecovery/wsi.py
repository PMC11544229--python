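"""Whole-slide raster tiling and tissue detection.

A whole-slide image (WSI) is far too large for a segmentation backend to
handle at once, so it is split into a grid of fixed-size square tiles
(default 256 px, matching common GPU memory constraints), processed per
tile, and the tile outputs are reassembled in their original order.  The
stained-tissue mask provides the denominator of the cell-area rate.

Conventions: 0-based row-major coordinates, half-open pixel boxes.  The
raster is padded on the right/bottom with pure white (the unstained
background color) up to the next multiple of the tile size; padding is
cropped again on reassembly and excluded from area statistics via the
tissue mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

WHITE_PIXEL = 255


def drop_small_blobs(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected components with fewer than ``min_px`` pixels."""
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


@dataclass(frozen=True)
class Tile:
    row: int
    col: int
    y0: int
    x0: int
    pixels: np.ndarray  # (T, T, 3) uint8


@dataclass(frozen=True)
class TileGrid:
    """Row-major tiling of a padded raster."""

    tile_size: int
    original_h: int
    original_w: int
    padded_h: int
    padded_w: int
    tiles: tuple[Tile, ...]

    @property
    def n_rows(self) -> int:
        return self.padded_h // self.tile_size

    @property
    def n_cols(self) -> int:
        return self.padded_w // self.tile_size

    def boxes(self) -> np.ndarray:
        """(n_tiles, 4) array of (row, col, y0, x0)."""
        return np.array([(t.row, t.col, t.y0, t.x0) for t in self.tiles])


def split_to_grid(image: np.ndarray, tile_size: int = 256) -> TileGrid:
    """Split an RGB raster into non-overlapping ``tile_size`` square tiles.

    The raster is padded with white on the right and bottom to the smallest
    multiple of ``tile_size``; tiles are emitted row-major and jointly cover
    the padded raster exactly once.
    """
    if tile_size < 8:
        raise ValueError(f"tile_size must be >= 8, got {tile_size}")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty raster")

    ph = -(-h // tile_size) * tile_size
    pw = -(-w // tile_size) * tile_size
    padded = np.full((ph, pw, 3), WHITE_PIXEL, dtype=image.dtype)
    padded[:h, :w] = image

    tiles = []
    for r in range(ph // tile_size):
        for c in range(pw // tile_size):
            y0, x0 = r * tile_size, c * tile_size
            tiles.append(
                Tile(r, c, y0, x0, padded[y0 : y0 + tile_size, x0 : x0 + tile_size])
            )
    return TileGrid(tile_size, h, w, ph, pw, tuple(tiles))


def reassemble(
    grid: TileGrid,
    tile_outputs: list[np.ndarray],
    original_h: int | None = None,
    original_w: int | None = None,
) -> np.ndarray:
    """Stitch per-tile outputs back to a full raster, cropping the padding.

    ``tile_outputs`` must contain one array per tile, in the grid's order;
    each must be ``tile_size`` square (2-D, or 3-D with any channel count).
    The inverse of :func:`split_to_grid`: a round trip is bit-exact.
    """
    h = grid.original_h if original_h is None else original_h
    w = grid.original_w if original_w is None else original_w
    if len(tile_outputs) != len(grid.tiles):
        raise ValueError(
            f"expected {len(grid.tiles)} tile outputs, got {len(tile_outputs)}"
        )
    if h == 0 or w == 0:
        first = tile_outputs[0] if tile_outputs else np.zeros((0, 0))
        shape = (h, w) + np.asarray(first).shape[2:]
        return np.zeros(shape, dtype=np.asarray(first).dtype)

    T = grid.tile_size
    first = np.asarray(tile_outputs[0])
    out_shape = (grid.padded_h, grid.padded_w) + first.shape[2:]
    out = np.zeros(out_shape, dtype=first.dtype)
    for tile, piece in zip(grid.tiles, tile_outputs):
        piece = np.asarray(piece)
        if piece.shape[:2] != (T, T):
            raise ValueError(f"tile output shape {piece.shape[:2]} != ({T}, {T})")
        out[tile.y0 : tile.y0 + T, tile.x0 : tile.x0 + T] = piece
    return out[:h, :w]


@dataclass(frozen=True)
class TissueMask:
    mask: np.ndarray  # 2-D bool

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def detect_tissue(
    image: np.ndarray,
    saturation_threshold: float = 0.08,
    min_blob_px: int = 64,
) -> TissueMask:
    """Detect the stained-tissue region of a slide.

    A pixel is tissue when its saturation (max minus min channel over the
    max channel; zero for pure white, black and grays) exceeds the
    threshold.  Connected blobs below ``min_blob_px`` pixels are discarded
    as debris and holes inside tissue are filled, so pale fiber interiors
    still count toward the stain area.
    """
    if not 0.0 <= saturation_threshold <= 1.0:
        raise ValueError("saturation_threshold must be in [0, 1]")
    img = np.asarray(image, dtype=np.float64)
    cmax = img.max(axis=2)
    cmin = img.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(cmax > 0, (cmax - cmin) / np.where(cmax > 0, cmax, 1), 0.0)
    mask = sat > saturation_threshold
    if min_blob_px > 1:
        mask = drop_small_blobs(mask, min_blob_px)
    mask = ndi.binary_fill_holes(mask)
    return TissueMask(mask)
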