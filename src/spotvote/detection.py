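"""Greedy particle read-out from a score map with circular suppression.

Repeatedly take the global maximum of the (copied) score map; if it is at
least the threshold, record a detection and overwrite every pixel within the
suppression radius (default 25, half the patch side) with -inf so nothing in
that disk can be selected again; stop when the remaining maximum falls below
the threshold.  Equal maxima are broken deterministically by smallest
row-major index.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .voting import ScoreMap

__all__ = ["Detection", "DetectionConfig", "detect"]


@dataclass(frozen=True)
class Detection:
    center: tuple[int, int]  # (row, col)
    score: float  # vote mass at selection time
    rank: int  # 1 = highest score


@dataclass(frozen=True)
class DetectionConfig:
    suppression_radius: int = 25
    threshold: float = 0.0
    max_detections: int | None = None

    def __post_init__(self) -> None:
        if self.suppression_radius < 1:
            raise ValueError("suppression_radius must be >= 1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@lru_cache(maxsize=None)
def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Offsets with exact Euclidean norm <= radius (the suppression disk)."""
    r = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(r, r, indexing="ij")
    keep = dr**2 + dc**2 <= radius**2
    return dr[keep], dc[keep]


def detect(score_map: ScoreMap | np.ndarray, config: DetectionConfig) -> list[Detection]:
    """Greedy maximum search with circular suppression.

    The input map is not mutated.  Returned detections are pairwise more
    than ``suppression_radius`` apart and ordered by non-increasing score.
    """
    values = score_map.values if isinstance(score_map, ScoreMap) else score_map
    work = np.array(values, dtype=float, copy=True)
    h, w = work.shape
    dr, dc = _disk_offsets(config.suppression_radius)
    detections: list[Detection] = []
    while True:
        if config.max_detections is not None and len(detections) >= config.max_detections:
            break
        flat = int(np.argmax(work))  # first (smallest row-major) max wins ties
        r, c = divmod(flat, w)
        val = work[r, c]
        if not np.isfinite(val) or val < config.threshold:
            break
        detections.append(
            Detection(center=(r, c), score=float(val), rank=len(detections) + 1)
        )
        rr = r + dr
        cc = c + dc
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        work[rr[keep], cc[keep]] = -np.inf
    return detections
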