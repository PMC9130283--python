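"""Single-cell feature table: per-ROI marker means plus nuclear centroids.

One row per segmented pseudo-cell.  Marker intensities are the mean of
the registered, autofluorescence-subtracted 8-bit image over the
expanded ROI; a linearly rescaled copy (0-1, value/255) is carried for
clustering and for transporter quantification.  Centroids are the
nuclear (pre-expansion) pixel centroids, in both px and um.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .panel import MarkerPanel
from .segmentation import LabelMask
from .stack import ImageStack

FIXED_COLUMNS = ["cell_id", "x_px", "y_px", "x_um", "y_um", "area_px"]


def table_columns(panel: MarkerPanel) -> list[str]:
    """Stable CSV schema: fixed columns, then raw means, then rescaled means."""
    names = panel.marker_names
    return FIXED_COLUMNS + [f"{m}_raw" for m in names] + [f"{m}_scaled" for m in names] + ["sample_id"]


def extract_features(
    stack: ImageStack,
    nuclei: LabelMask,
    cells: LabelMask,
    panel: MarkerPanel,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Mean marker intensity over each expanded ROI + nuclear centroids.

    `nuclei` provides centroids and nuclear areas; `cells` (the expanded
    mask, same label ids) defines the averaging region.
    """
    if cells.labels.shape != stack.shape:
        raise ValueError("label mask shape does not match image shape")
    missing = []
    imgs = {}
    for m in panel.marker_names:
        try:
            imgs[m] = stack.marker_image(panel, m)
        except KeyError:
            missing.append(m)
    if missing:
        raise KeyError(f"stack is missing image(s) for marker(s): {missing}")

    idx = nuclei.table["label"].to_numpy()
    mpp = stack.microns_per_pixel
    out = pd.DataFrame(
        {
            "cell_id": idx.astype(int),
            "x_px": nuclei.table["x"].to_numpy(),
            "y_px": nuclei.table["y"].to_numpy(),
            "x_um": nuclei.table["x"].to_numpy() * mpp,
            "y_um": nuclei.table["y"].to_numpy() * mpp,
            "area_px": nuclei.table["area"].to_numpy(),
        }
    )
    for m in panel.marker_names:
        if len(idx):
            means = ndi.mean(imgs[m].astype(np.float64), labels=cells.labels, index=idx)
        else:
            means = np.array([])
        out[f"{m}_raw"] = means
    for m in panel.marker_names:
        out[f"{m}_scaled"] = out[f"{m}_raw"] / 255.0
    out["sample_id"] = sample_id
    return out


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.6g")


def read_cell_table(path: str | Path, panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Read a cell table CSV; verifies the schema when a panel is given."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed cell table CSV {path}: {e}") from e
    if panel is not None:
        missing = [c for c in table_columns(panel) if c not in table.columns]
        if missing:
            raise ValueError(f"cell table {path} is missing column(s): {missing}")
    return table


def scaled_matrix(table: pd.DataFrame, markers: list[str]) -> np.ndarray:
    """Cell x marker matrix of rescaled (0-1) intensities for clustering."""
    missing = [m for m in markers if f"{m}_scaled" not in table.columns]
    if missing:
        raise ValueError(f"cell table is missing rescaled column(s) for: {missing}")
    return table[[f"{m}_scaled" for m in markers]].to_numpy(dtype=float)
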