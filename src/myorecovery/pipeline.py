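"""End-to-end slide inference: tiles -> cells -> features -> classes -> score.

For one slide the pipeline (i) splits the raster into 256 px grid tiles,
(ii) runs two segmentation passes per tile — a fixed small diameter of
5 px (Layer 0, catches myoblasts) and automatic diameter (Layer 1) —
(iii) reassembles full-slide label masks, (iv) crops a 64 px cell image
per centroid, extracts features and classifies each cell, (v) paints one
class raster per layer and overlays them prioritizing Layer 1, and (vi)
summarizes the slide with its class proportions over the cell area, the
cell-area rate over the stained-tissue area, and the recovery score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import segmentation as seg
from .classifier import RecoveryPhaseResults
from .features import ExtractorConfig, extract_features
from .recovery import (
    RecoveryScoreResults,
    RecoverySummary,
    classmap_proportions,
    recovery_score,
)
from .scheme import ClassScheme, DEFAULT_SCHEME, NO_DETECTION
from .wsi import detect_tissue, reassemble, split_to_grid

#: the two reference segmentation passes: Layer 0 fixed diameter 5 px,
#: Layer 1 automatic diameter; merged with Layer 1 priority.
DEFAULT_LAYERS = (
    seg.SegmenterConfig(backend="classical", diameter=5.0),
    seg.SegmenterConfig(backend="classical", diameter=None),
)


@dataclass
class SlideResult:
    """Everything inferred for one slide."""

    cells: pd.DataFrame              # one row per cell (both layers)
    class_raster: np.ndarray         # merged class map, NO_DETECTION elsewhere
    layer_rasters: tuple[np.ndarray, ...]
    label_masks: tuple[np.ndarray, ...]
    summary: RecoverySummary | None


def segment_slide(
    image: np.ndarray,
    config: seg.SegmenterConfig,
    tile_size: int = 256,
) -> np.ndarray:
    """Tile the slide, segment each tile, reassemble one full label mask.

    Labels are offset per tile so cell ids are unique slide-wide.
    """
    grid = split_to_grid(image, tile_size)
    outputs = []
    offset = 0
    for tile in grid.tiles:
        mask = seg.run_backend(tile.pixels, config).astype(np.int32)
        n = int(mask.max())
        mask = np.where(mask > 0, mask + offset, 0)
        offset += n
        outputs.append(mask)
    return reassemble(grid, outputs)


def classify_slide(
    image: np.ndarray,
    results: RecoveryPhaseResults,
    layers=DEFAULT_LAYERS,
    extractor: ExtractorConfig | None = None,
    tile_size: int = 256,
    crop_size: int = 64,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> SlideResult:
    """Segment, classify and color every cell of a slide (both layers)."""
    extractor = extractor or ExtractorConfig()
    layer_rasters = []
    label_masks = []
    records = []
    for li, layer_cfg in enumerate(layers):
        mask = segment_slide(image, layer_cfg, tile_size)
        label_masks.append(mask)
        cells = seg.extract_cells(mask)
        raster = np.full(image.shape[:2], NO_DETECTION, dtype=np.int32)
        if cells:
            crops = [seg.crop_cell(image, c.centroid, crop_size) for c in cells]
            feats = extract_features(crops, extractor)
            probs = results.predict_proba(feats)
            classes = np.argmax(probs, axis=1)
            for cell, cls, conf in zip(cells, classes, probs):
                raster[mask == cell.cell_id] = cls
                rec = {
                    "layer": li,
                    "cell_id": cell.cell_id,
                    "row": cell.centroid[0],
                    "col": cell.centroid[1],
                    "area_px": cell.area_px,
                    "pred_class": int(cls),
                    "pred_name": scheme.names[int(cls)],
                }
                rec.update({f"conf_{n}": float(c) for n, c in zip(scheme.names, conf)})
                records.append(rec)
        layer_rasters.append(raster)

    merged = seg.merge_layers(layer_rasters[0], layer_rasters[-1]) \
        if len(layer_rasters) > 1 else layer_rasters[0]
    cells_df = pd.DataFrame(records)
    return SlideResult(cells_df, merged, tuple(layer_rasters), tuple(label_masks), None)


def summarize_slide(
    image: np.ndarray,
    slide_result: SlideResult,
    score_results: RecoveryScoreResults | None = None,
    slide_id: str = "slide",
    day: int | None = None,
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> RecoverySummary:
    """Slide-level proportions, cell-area rate and recovery score."""
    cell_mask = slide_result.class_raster != NO_DETECTION
    proportions = classmap_proportions(slide_result.class_raster, cell_mask, scheme.K)
    tissue = detect_tissue(image)
    union = np.zeros(image.shape[:2], dtype=bool)
    for mask in slide_result.label_masks:
        union |= mask > 0
    rate = seg.cell_area_rate(union.astype(np.int32), tissue)
    score = score_results.score(proportions) if score_results is not None else float("nan")
    summary = RecoverySummary(slide_id, score, rate, proportions, day)
    slide_result.summary = summary
    return summary


def run_slide(
    image: np.ndarray,
    results: RecoveryPhaseResults,
    score_results: RecoveryScoreResults | None = None,
    slide_id: str = "slide",
    day: int | None = None,
    **kwargs,
) -> SlideResult:
    """Full inference + summary for one slide raster."""
    out = classify_slide(image, results, **kwargs)
    if len(out.cells):
        summarize_slide(image, out, score_results, slide_id, day)
    return out


def class_raster_to_rgb(
    class_raster: np.ndarray, scheme: ClassScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Colored class map: palette color per class, white where no cell."""
    out = np.full(class_raster.shape + (3,), 255, dtype=np.uint8)
    for k, color in enumerate(scheme.colors):
        out[class_raster == k] = color
    return out
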