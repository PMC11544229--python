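"""Cell segmentation backends and per-cell geometry.

The pipeline treats the instance segmenter as a pluggable backend.  The
reference study fine-tunes a generalist neural segmenter (cyto2-style,
grayscale channels ``(0, 0)``, otherwise default settings) and runs it in
two passes — a small fixed object diameter of 5 px ("Layer 0") and
automatic diameter ("Layer 1") — whose colored outputs are overlaid with
Layer 1 taking priority.  Neural weights are not distributed with this
package; instead:

* ``register_backend`` lets users wire any external segmenter that maps an
  RGB tile to an integer label mask;
* the built-in ``"classical"`` backend (grayscale conversion, adaptive
  threshold, distance-transform watershed with a minimum object scale tied
  to the diameter) is fully deterministic and keeps the whole pipeline
  testable offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, segmentation as sk_seg
from skimage.color import rgb2gray

from .scheme import NO_DETECTION
from .wsi import drop_small_blobs


@dataclass(frozen=True)
class SegmenterConfig:
    """Configuration of one segmentation pass.

    ``diameter=None`` means automatic scale estimation (the "Layer 1"
    setting); a positive float fixes the expected object diameter in
    pixels ("Layer 0" uses 5).  ``channels=(0, 0)`` declares grayscale
    segmentation with no separate nucleus channel, matching the settings
    used to fine-tune the external generalist model.
    """

    backend: str = "classical"
    diameter: float | None = None
    channels: tuple[int, int] = (0, 0)
    model_ref: str | None = None

    def __post_init__(self) -> None:
        if self.diameter is not None and self.diameter <= 0:
            raise ValueError("diameter must be positive or None (auto)")


@dataclass(frozen=True)
class CellObject:
    """One segmented cell in slide coordinates."""

    cell_id: int
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    bbox: tuple[int, int, int, int]  # (y0, x0, y1, x1), half-open
    contour: np.ndarray  # (n, 2) float boundary polygon
    tile_origin: tuple[int, int] = (0, 0)


BackendFn = Callable[[np.ndarray, SegmenterConfig], np.ndarray]
_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    """Register an external segmentation adapter under ``name``."""
    _BACKENDS[name] = fn


def run_backend(tile: np.ndarray, config: SegmenterConfig) -> np.ndarray:
    """Segment one RGB tile into an integer label mask (0 = background)."""
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB tile")
    if config.backend == "classical":
        return _classical_segment(tile, config.diameter)
    fn = _BACKENDS.get(config.backend)
    if fn is None:
        raise KeyError(
            f"unknown segmentation backend {config.backend!r}; "
            f"registered: {sorted(_BACKENDS)} + ['classical']"
        )
    return np.asarray(fn(tile, config))


def _classical_segment(tile: np.ndarray, diameter: float | None) -> np.ndarray:
    """Deterministic watershed segmentation of dark objects on white.

    Foreground is taken where the grayscale image is darker than a local
    adaptive threshold (with a small offset so flat white tiles stay
    empty) and clearly below paper-white; holes are filled so pale fiber
    interiors belong to their cell.  Touching objects are split by a
    watershed on the distance transform, seeded at distance peaks no
    closer than the object diameter; ``diameter=None`` estimates the scale
    from the median equivalent diameter of the foreground components.
    """
    gray = rgb2gray(tile) * 255.0
    block = 51 if min(tile.shape[:2]) >= 51 else max(3, (min(tile.shape[:2]) // 2) * 2 + 1)
    local = filters.threshold_local(gray, block_size=block, method="gaussian")
    fg = (gray < local - 2.0) & (gray < 245.0)
    fg = ndi.binary_fill_holes(fg)

    if not fg.any():
        return np.zeros(tile.shape[:2], dtype=np.int32)

    comps, _ = ndi.label(fg)
    if diameter is None:
        props = measure.regionprops(comps)
        eq = np.median([p.equivalent_diameter_area for p in props])
        diameter = float(max(4.0, eq))

    min_area = max(4, int(round(0.25 * math.pi * (diameter / 2.0) ** 2)))
    fg = drop_small_blobs(fg, min_area)
    if not fg.any():
        return np.zeros(tile.shape[:2], dtype=np.int32)

    distance = ndi.distance_transform_edt(fg)
    min_dist = max(2, int(round(0.8 * diameter)))
    comps, _ = ndi.label(fg)
    peaks = feature.peak_local_max(
        distance, min_distance=min_dist, labels=comps, exclude_border=False
    )
    marker_mask = np.zeros_like(fg, dtype=bool)
    marker_mask[tuple(peaks.T)] = True
    markers, n_markers = ndi.label(marker_mask)
    if n_markers == 0:
        labels, _ = ndi.label(fg)
        return labels.astype(np.int32)
    labels = sk_seg.watershed(-distance, markers, mask=fg)
    # components the peak detector skipped entirely keep their own label
    orphan = fg & (labels == 0)
    if orphan.any():
        extra, _ = ndi.label(orphan)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    return labels.astype(np.int32)


def extract_cells(
    mask: np.ndarray, tile_origin: tuple[int, int] = (0, 0)
) -> list[CellObject]:
    """Turn a label mask into :class:`CellObject` records.

    Centroids are arithmetic means of each label's pixel coordinates,
    shifted by ``tile_origin`` into slide coordinates; the contour traces
    the outer boundary at the 0.5 iso-level.
    """
    mask = np.asarray(mask)
    oy, ox = tile_origin
    cells: list[CellObject] = []
    for prop in measure.regionprops(mask.astype(np.int64)):
        y0, x0, y1, x1 = prop.bbox
        region = mask[y0:y1, x0:x1] == prop.label
        contours = measure.find_contours(np.pad(region.astype(float), 1), 0.5)
        contour = max(contours, key=len) if contours else np.zeros((0, 2))
        contour = contour - 1 + np.array([y0 + oy, x0 + ox])
        cells.append(
            CellObject(
                cell_id=int(prop.label),
                centroid=(prop.centroid[0] + oy, prop.centroid[1] + ox),
                area_px=int(prop.area),
                bbox=(y0 + oy, x0 + ox, y1 + oy, x1 + ox),
                contour=contour,
                tile_origin=(oy, ox),
            )
        )
    return cells


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def crop_cell(slide: np.ndarray, centroid: tuple[float, float], size: int = 64) -> np.ndarray:
    """Extract a ``size`` square patch centered on a cell centroid.

    The centroid is rounded half-away-from-zero to a pixel index; the crop
    box is ``[r - size/2, r + size/2)`` in each axis and pixels outside the
    slide are filled by edge replication, which preserves local stain
    statistics near borders.
    """
    if size % 2 != 0:
        raise ValueError("crop size must be even")
    slide = np.asarray(slide)
    r = _round_half_away(centroid[0])
    c = _round_half_away(centroid[1])
    half = size // 2
    y0, y1 = r - half, r + half
    x0, x1 = c - half, c + half
    h, w = slide.shape[:2]
    pad_top = max(0, -y0)
    pad_left = max(0, -x0)
    pad_bottom = max(0, y1 - h)
    pad_right = max(0, x1 - w)
    sub = slide[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)]
    if pad_top or pad_left or pad_bottom or pad_right:
        pads = ((pad_top, pad_bottom), (pad_left, pad_right)) + ((0, 0),) * (slide.ndim - 2)
        sub = np.pad(sub, pads, mode="edge")
    return sub


def merge_layers(
    layer0: np.ndarray, layer1: np.ndarray, sentinel: int = NO_DETECTION
) -> np.ndarray:
    """Overlay two class rasters, prioritizing layer 1 where it detected.

    Output pixel = layer-1 pixel wherever layer 1 has a detection (value
    differs from the sentinel), else the layer-0 pixel.
    """
    layer0 = np.asarray(layer0)
    layer1 = np.asarray(layer1)
    if layer0.shape != layer1.shape:
        raise ValueError(f"shape mismatch: {layer0.shape} vs {layer1.shape}")
    return np.where(layer1 != sentinel, layer1, layer0)


def cell_area_rate(mask: np.ndarray, tissue) -> float:
    """Segmented cell pixels inside tissue, divided by the stain area."""
    tissue_mask = tissue.mask if hasattr(tissue, "mask") else np.asarray(tissue)
    area = int(np.asarray(tissue_mask).sum())
    if area == 0:
        raise ValueError("tissue mask is empty: cell-area rate undefined")
    covered = int(((np.asarray(mask) > 0) & tissue_mask).sum())
    return covered / area
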