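"""File formats tying the pipeline stages together.

Rasters are PNG/TIFF (label masks as 16-bit single channel); tabular
interchange — per-cell records, feature matrices, day-proportion tables,
recovery summaries — is plain CSV with explicit headers; metrics are
JSON.  No binary lock-in anywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .recovery import DayProportionTable, RecoverySummary
from .scheme import ClassScheme, DEFAULT_SCHEME


# ---------------------------------------------------------------------------
# rasters

def read_raster(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(Image.open(path))


def write_raster(path, array: np.ndarray) -> None:
    path = Path(path)
    array = np.asarray(array)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, array)
    else:
        Image.fromarray(array).save(path)


def write_label_mask(path, mask: np.ndarray) -> None:
    """Write an integer label mask as 16-bit single-channel PNG/TIFF."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask does not fit in uint16")
    path = Path(path)
    mask16 = mask.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask16)
    else:
        Image.fromarray(mask16).save(path)


def read_label_mask(path) -> np.ndarray:
    return np.asarray(read_raster(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# tables

def cells_to_csv(path, cells_df: pd.DataFrame) -> None:
    cells_df.to_csv(path, index=False)


def cell_objects_to_csv(path, cells) -> None:
    """Write CellObject records as CSV (cell_id, centroid, area, bbox)."""
    rows = [
        {"cell_id": c.cell_id, "row": c.centroid[0], "col": c.centroid[1],
         "area_px": c.area_px, "y0": c.bbox[0], "x0": c.bbox[1],
         "y1": c.bbox[2], "x1": c.bbox[3]}
        for c in cells
    ]
    pd.DataFrame(rows, columns=["cell_id", "row", "col", "area_px",
                                "y0", "x0", "y1", "x1"]).to_csv(path, index=False)


def tile_boxes_to_csv(path, grid) -> None:
    """Write a TileGrid's boxes as CSV (row, col, y0, x0, tile_size)."""
    boxes = grid.boxes()
    df = pd.DataFrame(boxes, columns=["row", "col", "y0", "x0"])
    df["tile_size"] = grid.tile_size
    df.to_csv(path, index=False)


def features_to_csv(path, features: np.ndarray, cell_ids=None, days=None) -> None:
    features = np.asarray(features)
    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    if cell_ids is not None:
        df.insert(0, "cell_id", cell_ids)
    if days is not None:
        df.insert(1 if cell_ids is not None else 0, "day", days)
    df.to_csv(path, index=False)


def features_from_csv(path):
    df = pd.read_csv(path)
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    fcols.sort(key=lambda c: int(c[1:]))
    features = df[fcols].to_numpy(dtype=np.float64)
    days = df["day"].to_numpy() if "day" in df.columns else None
    cell_ids = df["cell_id"].to_numpy() if "cell_id" in df.columns else None
    return features, days, cell_ids


def proportions_to_csv(path, table: DayProportionTable) -> None:
    table.to_dataframe().to_csv(path, index=False)


def proportions_from_csv(path, scheme: ClassScheme = DEFAULT_SCHEME) -> DayProportionTable:
    df = pd.read_csv(path)
    proportions, counts = {}, {}
    for _, row in df.iterrows():
        day = int(row["day"])
        proportions[day] = np.array([row[f"p_{n}"] for n in scheme.names])
        if f"px_{scheme.names[0]}" in df.columns:
            counts[day] = np.array([row[f"px_{n}"] for n in scheme.names], dtype=np.int64)
        else:
            counts[day] = np.zeros(scheme.K, dtype=np.int64)
    return DayProportionTable(proportions, counts, scheme)


def summaries_to_csv(path, summaries: list[RecoverySummary],
                     scheme: ClassScheme = DEFAULT_SCHEME) -> None:
    rows = []
    for s in summaries:
        row = {
            "slide": s.slide_id,
            "day": s.day,
            "recovery_score": s.recovery_score,
            "cell_area_rate": s.cell_area_rate,
        }
        row.update({f"p_{n}": float(v) for n, v in zip(scheme.names, s.color_proportions)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def metrics_to_json(path, metrics: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, default=default)
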