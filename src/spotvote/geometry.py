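"""Integer ring geometry shared by patch labeling and score-patch voting.

The detector quantizes the Euclidean distance between a patch center and the
nearest particle center into integer classes ``0..R`` (``R`` = patch radius,
default 25, i.e. a 51x51 patch).  Voting inverts that quantization: the
probability mass assigned to class ``r`` is spread back over the ring of
pixels whose rounded distance from the patch center is ``r``.  Labeling and
voting are exact adjoints because both use the same rounding rule
(round half up): a particle sitting at offset ``o`` from a patch center is
labeled class ``r`` exactly when voting class ``r`` deposits mass on ``o``.

Coordinates are 0-based ``(row, col)`` with row increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "PatchGeometry",
    "rounded_distance",
    "ring_offsets",
    "ring_sizes",
    "disk_offsets",
    "offset_distance_map",
]


@dataclass(frozen=True)
class PatchGeometry:
    """Square patch of side ``2*radius + 1`` centered on a pixel.

    ``radius`` is simultaneously the patch half-side and the largest distance
    class: a particle farther than ``radius`` (rounded) from the patch center
    is out of range and the patch is negative.
    """

    radius: int = 25

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")

    @property
    def side(self) -> int:
        return 2 * self.radius + 1

    @property
    def n_distance_classes(self) -> int:
        """Number of positive (distance) classes: 0..radius inclusive."""
        return self.radius + 1

    @property
    def n_classes(self) -> int:
        """Distance classes plus the negative class (27 for radius 25)."""
        return self.radius + 2

    @property
    def negative_index(self) -> int:
        """Column index of the negative class in a class-score vector."""
        return self.radius + 1


def rounded_distance(a, b) -> int:
    """Round-half-up Euclidean distance between two pixel positions.

    Symmetric, and zero iff ``a == b`` (round-half-up maps d < 0.5 to 0 and
    the minimum nonzero pixel distance is 1).
    """
    dr = float(a[0]) - float(b[0])
    dc = float(a[1]) - float(b[1])
    return int(np.floor(np.hypot(dr, dc) + 0.5))


@lru_cache(maxsize=None)
def offset_distance_map(geom: PatchGeometry) -> np.ndarray:
    """``side x side`` map of rounded distances from the patch center.

    Values at the patch corners exceed ``radius`` (up to round(R*sqrt(2)));
    those offsets belong to no ring.
    """
    r = np.arange(-geom.radius, geom.radius + 1, dtype=float)
    dist = np.hypot(r[:, None], r[None, :])
    out = np.floor(dist + 0.5).astype(np.int64)
    out.setflags(write=False)
    return out


def ring_offsets(r: int, geom: PatchGeometry = PatchGeometry()) -> set[tuple[int, int]]:
    """All in-patch offsets ``(drow, dcol)`` at rounded distance exactly ``r``.

    Rings for r = 0..radius are pairwise disjoint and together cover the
    rounded-distance-<= radius disk.
    """
    if not 0 <= r <= geom.radius:
        raise ValueError(
            f"distance class must be in 0..{geom.radius}, got {r}"
        )
    dmap = offset_distance_map(geom)
    rows, cols = np.nonzero(dmap == r)
    return {(int(i) - geom.radius, int(j) - geom.radius) for i, j in zip(rows, cols)}


@lru_cache(maxsize=None)
def ring_sizes(geom: PatchGeometry) -> np.ndarray:
    """Pixel count of each ring r = 0..radius (read-only int array)."""
    dmap = offset_distance_map(geom)
    sizes = np.bincount(dmap.ravel(), minlength=geom.radius + 1)[: geom.radius + 1]
    sizes = sizes.copy()
    sizes.setflags(write=False)
    return sizes


def disk_offsets(geom: PatchGeometry = PatchGeometry()) -> set[tuple[int, int]]:
    """All offsets with rounded Euclidean norm <= radius (union of all rings)."""
    dmap = offset_distance_map(geom)
    rows, cols = np.nonzero(dmap <= geom.radius)
    return {(int(i) - geom.radius, int(j) - geom.radius) for i, j in zip(rows, cols)}
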