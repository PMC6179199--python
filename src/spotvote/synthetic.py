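"""Synthetic fluorescence-microscopy-like images with known particle centers.

Cell particles in the images this package targets are small bright roughly
circular blobs ("light spots") with ambiguous edges, often overlapping in
dense regions, on a noisy background.  The generator emulates exactly that:
isotropic Gaussian intensity profiles at known (sub-pixel) centers, a
configurable fraction of particles deliberately placed within one particle
diameter of an existing particle so their profiles merge, additive Gaussian
pixel noise, and optional saturation clipping.

It also provides the ground-truth perturbation used to study robustness to
annotation subjectivity: each training center is displaced by an independent
uniform integer offset with Chebyshev norm at most ``error_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SyntheticSpec", "GroundTruth", "generate_image", "perturb_ground_truth"]


@dataclass(frozen=True)
class GroundTruth:
    """Known particle centers of one image.

    ``centers`` is an ``(n, 2)`` float array of ``(row, col)`` positions
    (sub-pixel positions allowed; labeling rounds them).
    """

    centers: np.ndarray
    image_id: str = ""
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.size == 0:
            centers = centers.reshape(0, 2)
        if centers.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array of (row, col)")
        object.__setattr__(self, "centers", centers)
        if self.image_shape is not None:
            h, w = self.image_shape
            if centers.size and (
                centers[:, 0].min() < 0
                or centers[:, 1].min() < 0
                or centers[:, 0].max() > h - 1
                or centers[:, 1].max() > w - 1
            ):
                raise ValueError("ground-truth center outside image bounds")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic image.

    Intensities are in normalized units [0, 1]; images are exported as 8-bit
    grayscale by I/O helpers.  ``particle_radius_mean`` is the Gaussian sigma
    of a spot in pixels.  ``cluster_fraction`` of the particles are placed
    within one particle diameter (2 sigma) of an already placed particle,
    which creates merged/overlapping spots; the remaining particles keep a
    minimum pairwise separation of ``min_separation`` pixels.  ``margin``
    keeps every center far enough from the border that a full patch centered
    on it fits inside the image.
    """

    height: int = 256
    width: int = 256
    n_particles: int = 30
    particle_radius_mean: float = 3.0
    particle_radius_sd: float = 0.5
    peak_intensity_range: tuple[float, float] = (0.4, 0.9)
    background_level: float = 0.08
    noise_sd: float = 0.03
    cluster_fraction: float = 0.1
    min_separation: float = 28.0
    margin: int = 26
    saturation_clip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.peak_intensity_range
        if not 0 < lo <= hi:
            raise ValueError("peak_intensity_range must satisfy 0 < lo <= hi")


_MAX_ATTEMPTS_PER_PARTICLE = 300


def _place_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample particle centers: isolated ones keep min_separation,
    clustered ones are pinned within one diameter of an earlier particle."""
    n = spec.n_particles
    if n == 0:
        return np.zeros((0, 2))
    n_cluster = int(np.floor(spec.cluster_fraction * n))
    n_cluster = min(n_cluster, n - 1)  # a clustered particle needs a host
    n_free = n - n_cluster

    lo_r, hi_r = spec.margin, spec.height - 1 - spec.margin
    lo_c, hi_c = spec.margin, spec.width - 1 - spec.margin
    if lo_r >= hi_r or lo_c >= hi_c:
        raise ValueError("image too small for the requested margin")

    centers: list[np.ndarray] = []
    attempts = 0
    budget = _MAX_ATTEMPTS_PER_PARTICLE * n
    while len(centers) < n_free:
        if attempts > budget:
            raise RuntimeError(
                f"could not place {n} particles at separation "
                f"{spec.min_separation} in a {spec.height}x{spec.width} image"
            )
        attempts += 1
        cand = np.array(
            [rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)]
        )
        if all(np.hypot(*(cand - c)) >= spec.min_separation for c in centers):
            centers.append(cand)

    diameter = 2.0 * spec.particle_radius_mean
    while len(centers) < n:
        if attempts > budget:
            raise RuntimeError("could not place clustered particles")
        attempts += 1
        host = centers[rng.integers(0, n_free)]
        dist = rng.uniform(0.5 * diameter, diameter)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        cand = host + dist * np.array([np.sin(ang), np.cos(ang)])
        if not (lo_r <= cand[0] <= hi_r and lo_c <= cand[1] <= hi_c):
            continue
        # keep clusters pairwise tight with their host but clear of others
        others = [c for c in centers if c is not host]
        if all(np.hypot(*(cand - c)) >= diameter for c in others):
            centers.append(cand)
    return np.array(centers)


def generate_image(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic image and its ground truth.

    Returns ``(image, truth)`` where ``image`` is ``(height, width)``
    float64 in [0, 1] and ``truth.centers`` holds the exact sub-pixel
    particle centers.  Identical spec (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)

    img = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    rows = np.arange(spec.height, dtype=float)[:, None]
    cols = np.arange(spec.width, dtype=float)[None, :]
    lo_a, hi_a = spec.peak_intensity_range
    for cr, cc in centers:
        sigma = rng.normal(spec.particle_radius_mean, spec.particle_radius_sd)
        sigma = max(sigma, 0.3 * spec.particle_radius_mean)
        amp = rng.uniform(lo_a, hi_a)
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        img += amp * np.exp(-d2 / (2.0 * sigma**2))

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.saturation_clip:
        img = np.clip(img, 0.0, 1.0)

    truth = GroundTruth(
        centers=centers,
        image_id=f"synthetic-{spec.seed}",
        image_shape=(spec.height, spec.width),
    )
    return img, truth


def perturb_ground_truth(
    truth: GroundTruth, error_range: int, seed: int
) -> GroundTruth:
    """Displace each center by an independent uniform integer offset in
    ``[-error_range, error_range]^2`` (Chebyshev ball), clipped to bounds.

    Emulates subjective annotation error in training data; ``error_range=0``
    is the identity.
    """
    if error_range < 0:
        raise ValueError("error_range must be >= 0")
    if error_range == 0 or len(truth) == 0:
        return truth
    rng = np.random.default_rng(seed)
    offsets = rng.integers(-error_range, error_range + 1, size=truth.centers.shape)
    centers = truth.centers + offsets
    if truth.image_shape is not None:
        h, w = truth.image_shape
        centers[:, 0] = np.clip(centers[:, 0], 0, h - 1)
        centers[:, 1] = np.clip(centers[:, 1], 0, w - 1)
    return replace(truth, centers=centers)
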