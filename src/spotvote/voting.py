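"""Ring voting: class scores -> score patches -> accumulated score map.

Each scanned patch contributes a *score patch*: the classifier probability
of distance class r is spread over the ring of pixels at rounded distance r
from the patch center (the negative-class probability is discarded — it
already suppressed the positive scores through the softmax).  By default the
class probability is divided equally among its ring's pixels so total vote
mass is conserved and large rings cannot outvote small ones; the plain copy
variant is available via ``mode="copy"``.

Score patches from every valid patch center on the stride grid (patches
fully inside the image; no padding) are summed into an image-sized score
map whose peaks are particle-center hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .geometry import PatchGeometry, offset_distance_map, ring_sizes

__all__ = [
    "ScoreMap",
    "make_score_patch",
    "valid_centers",
    "accumulate_score_map",
    "accumulate_positions",
    "accumulate_center_score_map",
]


@dataclass(frozen=True)
class ScoreMap:
    """Image-sized accumulator of vote mass; peaks mark particle centers."""

    values: np.ndarray  # (H, W) float, >= 0
    stride: int = 1


@lru_cache(maxsize=None)
def _ring_basis(geom: PatchGeometry, mode: str) -> np.ndarray:
    """Kernels (n_classes, side, side): kernel r is the ring of radius r with
    per-pixel weight 1/|ring| ("divide") or 1 ("copy"); the negative-class
    kernel is all zero."""
    if mode not in ("divide", "copy"):
        raise ValueError(f"unknown ring mode {mode!r}")
    dmap = offset_distance_map(geom)
    sizes = ring_sizes(geom)
    basis = np.zeros((geom.n_classes, geom.side, geom.side))
    for r in range(geom.radius + 1):
        ring = dmap == r
        basis[r][ring] = 1.0 / sizes[r] if mode == "divide" else 1.0
    basis.setflags(write=False)
    return basis


def make_score_patch(
    scores: np.ndarray, geom: PatchGeometry = PatchGeometry(), mode: str = "divide"
) -> np.ndarray:
    """Distribute class scores onto their rings -> (side, side) vote mass.

    Under ``mode="divide"`` the total mass equals the sum of the positive
    class scores exactly; negative-class mass is discarded.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (geom.n_classes,):
        raise ValueError(f"expected {geom.n_classes} class scores, got {scores.shape}")
    if (scores < 0).any():
        raise ValueError("class scores must be nonnegative")
    return np.tensordot(scores, _ring_basis(geom, mode), axes=1)


def valid_centers(
    shape: tuple[int, int], geom: PatchGeometry, stride: int = 1
) -> np.ndarray:
    """Patch centers on the stride grid whose patch lies fully inside."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    R = geom.radius
    h, w = shape
    if h < geom.side or w < geom.side:
        raise ValueError(f"image {shape} smaller than one {geom.side}x{geom.side} patch")
    rows = np.arange(R, h - R, stride)
    cols = np.arange(R, w - R, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def accumulate_positions(
    shape: tuple[int, int],
    centers: np.ndarray,
    scores: np.ndarray,
    geom: PatchGeometry = PatchGeometry(),
    mode: str = "divide",
) -> np.ndarray:
    """Reference scatter-add accumulation over an explicit position list.

    Adds the score patch of ``scores[i]`` centered at ``centers[i]``; the
    visiting order cannot affect the result beyond float rounding.
    """
    out = np.zeros(shape)
    R = geom.radius
    for (r, c), sc in zip(np.asarray(centers, dtype=int), np.asarray(scores)):
        out[r - R : r + R + 1, c - R : c + R + 1] += make_score_patch(sc, geom, mode)
    return out


def _accumulate_fft(
    shape: tuple[int, int],
    centers: np.ndarray,
    scores: np.ndarray,
    geom: PatchGeometry,
    mode: str,
) -> np.ndarray:
    """Fast path: one convolution per class of its probability lattice with
    its ring kernel; equal to the scatter-add up to float rounding."""
    basis = _ring_basis(geom, mode)
    out = np.zeros(shape)
    rows = np.asarray(centers)[:, 0].astype(int)
    cols = np.asarray(centers)[:, 1].astype(int)
    lattice = np.zeros(shape)
    for k in range(geom.radius + 1):  # negative class casts no votes
        col = np.asarray(scores)[:, k]
        if not col.any():
            continue
        lattice[:] = 0.0
        np.add.at(lattice, (rows, cols), col)
        out += signal.fftconvolve(lattice, basis[k], mode="same")
    return np.maximum(out, 0.0)  # clip fft rounding residue (~1e-15)


def accumulate_score_map(
    image: np.ndarray,
    scorer,
    geom: PatchGeometry = PatchGeometry(),
    stride: int = 1,
    mode: str = "divide",
    engine: str = "fft",
) -> ScoreMap:
    """Scan ``image`` with ``scorer`` and vote every score patch into a map.

    ``scorer`` must provide ``score_positions(image, centers) -> (n, K)``
    (any fitted classifier from :mod:`spotvote.classifier`, or the oracle).
    """
    centers = valid_centers(image.shape, geom, stride)
    scores = np.asarray(scorer.score_positions(image, centers))
    if engine == "fft":
        values = _accumulate_fft(image.shape, centers, scores, geom, mode)
    elif engine == "loop":
        values = accumulate_positions(image.shape, centers, scores, geom, mode)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return ScoreMap(values=values, stride=stride)


def accumulate_center_score_map(
    image: np.ndarray,
    scorer,
    geom: PatchGeometry = PatchGeometry(),
    stride: int = 1,
    positive_index: int = 1,
) -> ScoreMap:
    """Baseline map for the binary classifier: the particle probability is
    voted at the patch center only (no ring spreading)."""
    centers = valid_centers(image.shape, geom, stride)
    scores = np.asarray(scorer.score_positions(image, centers))
    values = np.zeros(image.shape)
    np.add.at(
        values,
        (centers[:, 0].astype(int), centers[:, 1].astype(int)),
        scores[:, positive_index],
    )
    return ScoreMap(values=values, stride=stride)
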