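"""Reading and writing of fields, masks, ground truth and configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synth import CHANNELS, GroundTruth, ImageField


def write_field_tiff(field: ImageField, path) -> Path:
    """Multichannel TIFF, axes CZYX, spacing stored in the metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        field.data.astype(np.float32),
        metadata={
            "axes": "CZYX",
            "channels": list(CHANNELS),
            "spacing_um": list(field.spacing),
            "field_id": field.field_id,
        },
    )
    return path


def read_field_tiff(path) -> ImageField:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except Exception as exc:
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    if data.ndim != 4 or data.shape[0] != len(CHANNELS):
        raise ValueError(
            f"malformed TIFF {path}: expected shape (3, nz, ny, nx), got {data.shape}"
        )
    spacing = tuple(meta.get("spacing_um", (0.5, 0.1, 0.1)))
    field_id = meta.get("field_id", path.stem)
    return ImageField(data=data.astype(np.float32), spacing=spacing, field_id=field_id)


def write_label_mask(mask3d: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask3d.astype(np.uint16))
    return path


def write_ground_truth_json(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_jsonable(), indent=1))
    return path


def load_ground_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
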