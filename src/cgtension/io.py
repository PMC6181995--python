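"""File-format glue: CSV trajectories/tables, 16-bit TIFF images, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import UptakeRecord


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a 2-D image or 3-D stack as 16-bit TIFF (values clipped)."""
    arr = np.clip(np.round(np.asarray(image)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_labels_tiff(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))


def uptake_records_to_csv(records: list[UptakeRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
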