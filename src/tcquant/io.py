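"""Reading and writing the plain-file interchange formats.

Patches are 8-bit RGB PNG; label maps are 16-bit single-channel TIFF;
truth/score tables are CSV with documented headers; tumour-bed polygons are
CSV vertex lists (columns ``x,y`` in slide pixels).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image


def write_patch_png(rgb: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(rgb, np.uint8)).save(path, format="PNG")


def read_patch(path) -> np.ndarray:
    img = np.asarray(Image.open(path).convert("RGB"))
    return img


def write_label_tiff(label_map: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(label_map, np.uint16))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_truth_csv(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("patch_id", "row", "col", "true_tc_percent") if c in table]
    table[cols].to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if not {"patch_id", "score"} <= set(table.columns):
        raise ValueError(f"{path}: expected columns patch_id,score")
    return table


def write_scores_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_polygon_csv(polygon: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(polygon, float), columns=["x", "y"]).to_csv(
        path, index=False
    )


def read_polygon_csv(path) -> np.ndarray:
    table = pd.read_csv(path)
    if not {"x", "y"} <= set(table.columns):
        raise ValueError(f"{path}: expected columns x,y")
    return table[["x", "y"]].to_numpy(float)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
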