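"""File formats: grayscale images, annotation/detection CSV, YAML config.

External point annotations use the common convention ``(x=column, y=row)``,
0-based; everything internal is ``(row, col)``.  Conversion happens only
here, at the I/O boundary.  Images are read as 8/16-bit grayscale PNG/TIFF
and normalized to float in [0, 1]; multi-channel inputs are collapsed by
luminance with a warning.  Score maps are exported as 32-bit float
single-channel TIFF.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import Detection
from .synthetic import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "read_score_map",
    "write_score_map",
    "read_annotations",
    "write_annotations",
    "read_detections",
    "write_detections",
    "RunConfig",
]

log = logging.getLogger("spotvote")

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path) -> np.ndarray:
    """Load a grayscale image as float64 in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        log.warning("%s is multi-channel; converting by luminance", path)
        arr = arr[..., :3].astype(float) @ _LUMA
        return arr / np.iinfo(np.uint8).max if arr.max() > 1.5 else arr
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def write_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_score_map(values: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def read_score_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def read_annotations(path, bounds: dict[str, tuple[int, int]] | None = None):
    """Read a center-annotation CSV (header ``image_id,x,y``) into a map
    image_id -> :class:`GroundTruth`.  Sub-pixel coordinates are preserved.

    ``bounds`` optionally maps image_id -> (height, width) for validation.
    Raises ``ValueError`` naming the offending row on malformed input.
    """
    df = pd.read_csv(path, dtype={"image_id": str})
    required = {"image_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: annotation CSV must have header image_id,x,y "
            f"(got {list(df.columns)})"
        )
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric {col!r} at row {row}")
        df[col] = vals
    if df[["x", "y"]].isna().any().any():
        row = int(np.nonzero(df[["x", "y"]].isna().any(axis=1).to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: missing coordinate at row {row}")
    out: dict[str, GroundTruth] = {}
    for image_id, grp in df.groupby("image_id", sort=True):
        centers = np.column_stack([grp["y"].to_numpy(), grp["x"].to_numpy()])
        shape = bounds.get(image_id) if bounds else None
        out[image_id] = GroundTruth(
            centers=centers, image_id=str(image_id), image_shape=shape
        )
    return out


def write_annotations(truths: dict[str, GroundTruth] | list[GroundTruth], path) -> None:
    """Write ground truths to the annotation CSV schema (x=col, y=row)."""
    if isinstance(truths, dict):
        items = truths.values()
    else:
        items = truths
    records = [
        {"image_id": t.image_id, "x": c[1], "y": c[0]}
        for t in items
        for c in t.centers
    ]
    pd.DataFrame.from_records(records, columns=["image_id", "x", "y"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_detections(detections: dict[str, list[Detection]], path) -> None:
    """Write detections as CSV ``image_id,x,y,score,rank``, grouped by image
    and rank-ordered; scores kept to 6 decimals."""
    records = [
        {
            "image_id": image_id,
            "x": d.center[1],
            "y": d.center[0],
            "score": d.score,
            "rank": d.rank,
        }
        for image_id in sorted(detections)
        for d in sorted(detections[image_id], key=lambda d: d.rank)
    ]
    pd.DataFrame.from_records(
        records, columns=["image_id", "x", "y", "score", "rank"]
    ).to_csv(path, index=False, float_format="%.6f")


def read_detections(path) -> dict[str, list[Detection]]:
    df = pd.read_csv(path, dtype={"image_id": str})
    out: dict[str, list[Detection]] = {}
    for image_id, grp in df.groupby("image_id", sort=True):
        out[image_id] = [
            Detection(center=(int(r.y), int(r.x)), score=float(r.score), rank=int(r.rank))
            for r in grp.sort_values("rank").itertuples()
        ]
    return out


@dataclass
class RunConfig:
    """Resolved run configuration (echoed to the output directory)."""

    patch_radius: int = 25
    stride: int = 5
    n_positive: int | None = 5000
    negative_ratio: float = 1.0
    epochs: int = 150
    batch_size: int = 256
    learning_rate: float = 1e-3
    suppression_radius: int | None = None
    threshold: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
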