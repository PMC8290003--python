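"""Reading and writing the pipeline's on-disk formats.

Images travel as multi-page 16-bit grayscale TIFF (page 1 = nuclear stain,
page 2 = TF channel); label masks as 16-bit TIFF; ground truth and configs
as JSON; per-cell, per-sample and Ct tables as CSV with a header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import SampleImage

__all__ = [
    "write_sample_tiff",
    "read_sample_tiff",
    "write_labels_tiff",
    "read_labels_tiff",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "config_to_json",
    "config_from_json",
]


def write_sample_tiff(image: SampleImage, path: str | Path) -> None:
    """Write a two-page 16-bit TIFF (nuclear page first). Intensities are
    rounded and clipped to the uint16 range."""
    stack = np.stack([image.nuclear_channel, image.tf_channel])
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_sample_tiff(
    path: str | Path, sample_id: str | None = None, pixel_size_um: float | None = None
) -> SampleImage:
    """Read a two-page TIFF into a SampleImage (page 1 nuclear, page 2 TF)."""
    data = tifffile.imread(path)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError(f"{path}: expected a multi-page TIFF with 2 channel pages")
    return SampleImage(
        nuclear_channel=data[0].astype(float),
        tf_channel=data[1].astype(float),
        sample_id=sample_id or Path(path).stem,
        pixel_size_um=pixel_size_um,
    )


def write_labels_tiff(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit storage")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_ground_truth_json(truth: pd.DataFrame, path: str | Path) -> None:
    records = truth.to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1, default=_jsonify))


def read_ground_truth_json(path: str | Path) -> pd.DataFrame:
    return pd.DataFrame(json.loads(Path(path).read_text()))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def config_to_json(config, path: str | Path) -> None:
    """Serialize a (nested) config dataclass to JSON."""
    Path(path).write_text(
        json.dumps(dataclasses.asdict(config), indent=1, default=_jsonify)
    )


def config_from_json(cls, path: str | Path):
    """Load a flat config dataclass from JSON, coercing list fields to tuples."""
    raw = json.loads(Path(path).read_text())
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in raw:
            value = raw[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
    return cls(**kwargs)
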