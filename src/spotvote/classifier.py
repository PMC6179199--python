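"""Pluggable patch classifiers: distance (27-way), binary baseline, oracle.

The learned classifiers are scikit-learn estimators (``fit`` /
``predict_proba`` / ``get_params``) built from a multilayer perceptron over
*radial ring statistics* of the patch: per-ring mean and maximum intensity
for rings r = 0..R plus the out-of-range corner region.  A distance class is
rotationally symmetric by construction — every position on the circle of
radius r around a particle carries the same label — so rotation-invariant
radial features are the natural inductive bias for this task, and they make
both training and dense whole-image scoring cheap (the per-ring statistics of
every pixel are separable image filters).

``OracleDistanceClassifier`` emits the one-hot ground-truth label and lets
the voting/detection stack be tested independently of any learning error.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from functools import lru_cache
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .geometry import PatchGeometry, offset_distance_map
from .labeling import NEGATIVE, TrainingPatch, label_patch
from .synthetic import GroundTruth

__all__ = [
    "ClassifierConfig",
    "DistancePatchClassifier",
    "BinaryPatchClassifier",
    "OracleDistanceClassifier",
    "train",
    "predict",
    "oracle_predict",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# radial features


@lru_cache(maxsize=None)
def _region_masks(geom: PatchGeometry) -> np.ndarray:
    """Boolean masks (R+2, side, side): rings 0..R then the corner region."""
    dmap = offset_distance_map(geom)
    masks = np.stack(
        [dmap == r for r in range(geom.radius + 1)] + [dmap > geom.radius]
    )
    masks.setflags(write=False)
    return masks


def patch_features(patches: np.ndarray, geom: PatchGeometry) -> np.ndarray:
    """Per-ring mean and max of each patch -> (n, 2*(R+2)) feature matrix."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim == 2:
        patches = patches[None]
    if patches.shape[-2:] != (geom.side, geom.side):
        raise ValueError(
            f"patch side {patches.shape[-2:]} does not match geometry "
            f"{geom.side}x{geom.side}"
        )
    masks = _region_masks(geom)
    flat = patches.reshape(len(patches), -1)
    mflat = masks.reshape(len(masks), -1)
    counts = mflat.sum(axis=1)
    means = flat @ mflat.T.astype(float) / counts
    maxes = np.empty_like(means)
    for k in range(len(masks)):
        maxes[:, k] = flat[:, mflat[k]].max(axis=1)
    return np.hstack([means, maxes])


def image_position_features(
    image: np.ndarray, centers: np.ndarray, geom: PatchGeometry
) -> np.ndarray:
    """Radial features of the patches centered at ``centers``, computed with
    whole-image filters (ring means via convolution, ring maxima via a
    maximum filter) instead of cropping patches one by one.

    Agrees with :func:`patch_features` at every fully-inside center.
    """
    image = np.asarray(image, dtype=np.float64)
    masks = _region_masks(geom)
    centers = np.asarray(centers, dtype=int)
    rows, cols = centers[:, 0], centers[:, 1]
    n_regions = len(masks)
    out = np.empty((len(centers), 2 * n_regions))
    for k, mask in enumerate(masks):
        kern = mask.astype(float) / mask.sum()
        mean_map = signal.fftconvolve(image, kern, mode="same")
        out[:, k] = mean_map[rows, cols]
        max_map = ndimage.maximum_filter(image, footprint=mask, mode="nearest")
        out[:, n_regions + k] = max_map[rows, cols]
    return out


def _raw_features(patches: np.ndarray, geom: PatchGeometry) -> np.ndarray:
    """Flattened 3x-downsampled pixels (fallback feature mode)."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim == 2:
        patches = patches[None]
    return patches[:, ::3, ::3].reshape(len(patches), -1)


# ---------------------------------------------------------------------------
# estimators


class _RadialMLPBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery; subclasses fix the label space."""

    #: number of score columns; set by subclass property
    def __init__(
        self,
        patch_radius: int = 25,
        hidden_layer_sizes: tuple[int, ...] = (96, 64),
        epochs: int = 150,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        features: str = "radial",
        random_state: int = 0,
    ):
        self.patch_radius = patch_radius
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.features = features
        self.random_state = random_state

    # -- label mapping, defined by subclasses -------------------------------
    @property
    def _geom(self) -> PatchGeometry:
        return PatchGeometry(self.patch_radius)

    def _n_score_classes(self) -> int:
        raise NotImplementedError

    def _encode(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _decode(self, idx: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- features ------------------------------------------------------------
    def _featurize_patches(self, X: np.ndarray) -> np.ndarray:
        if self.features == "radial":
            return patch_features(X, self._geom)
        if self.features == "raw":
            return _raw_features(X, self._geom)
        raise ValueError(f"unknown feature mode {self.features!r}")

    @staticmethod
    def _split_patches(X) -> tuple[np.ndarray, np.ndarray | None]:
        if len(X) and isinstance(X[0], TrainingPatch):
            pixels = np.stack([p.pixels for p in X])
            labels = np.array([p.label for p in X])
            return pixels, labels
        return np.asarray(X), None

    # -- sklearn api ---------------------------------------------------------
    def fit(self, X, y=None):
        """Fit on patches: ``X`` is (n, side, side) pixels (plus ``y``
        labels) or a list of :class:`TrainingPatch`."""
        pixels, patch_labels = self._split_patches(X)
        if y is None:
            y = patch_labels
        if y is None or len(pixels) == 0:
            raise ValueError("training requires non-empty patches and labels")
        y = np.asarray(y)
        if len(y) != len(pixels):
            raise ValueError("X and y length mismatch")
        geom = self._geom
        if pixels.shape[-2:] != (geom.side, geom.side):
            raise ValueError(
                f"patches are {pixels.shape[-2:]}, expected {geom.side}x{geom.side}"
            )
        codes = self._encode(y)
        feats = self._featurize_patches(pixels)
        self.model_ = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=self.hidden_layer_sizes,
                        max_iter=self.epochs,
                        batch_size=min(self.batch_size, len(pixels)),
                        learning_rate_init=self.learning_rate,
                        random_state=self.random_state,
                        alpha=1e-4,
                    ),
                ),
            ]
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self.model_.fit(feats, codes)
        self.geom_ = geom
        self.classes_ = self._decode(self.model_.named_steps["mlp"].classes_)
        self.loss_ = float(self.model_.named_steps["mlp"].loss_)
        self.train_accuracy_ = float(self.model_.score(feats, codes))
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")

    def _proba_from_features(self, feats: np.ndarray) -> np.ndarray:
        mlp = self.model_.named_steps["mlp"]
        raw = self.model_.predict_proba(feats)
        out = np.zeros((len(feats), self._n_score_classes()))
        out[:, mlp.classes_] = raw
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Class-score matrix (n, n_classes); rows sum to 1 (softmax)."""
        self._check_fitted()
        pixels, _ = self._split_patches(X)
        single = pixels.ndim == 2
        feats = self._featurize_patches(pixels)
        out = self._proba_from_features(feats)
        return out[0] if single else out

    def predict(self, X) -> np.ndarray:
        idx = np.argmax(np.atleast_2d(self.predict_proba(X)), axis=1)
        return self._decode(idx)

    def score_positions(self, image: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """Class scores of the patches centered at ``centers`` in ``image``,
        via whole-image radial filters (the fast path used by voting)."""
        self._check_fitted()
        if self.features == "radial":
            feats = image_position_features(image, centers, self.geom_)
        else:
            from .labeling import extract_patch

            patches = np.stack(
                [extract_patch(image, c, self.geom_) for c in np.asarray(centers)]
            )
            feats = self._featurize_patches(patches)
        return self._proba_from_features(feats)


class DistancePatchClassifier(_RadialMLPBase):
    """R+2-way classifier of the rounded distance from patch center to the
    nearest particle center (classes 0..R, plus NEGATIVE as the last column).
    """

    def _n_score_classes(self) -> int:
        return self._geom.n_classes

    def _encode(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=int)
        bad = (y > self._geom.radius) | ((y < 0) & (y != NEGATIVE))
        if bad.any():
            raise ValueError(
                f"labels must be 0..{self._geom.radius} or NEGATIVE ({NEGATIVE})"
            )
        return np.where(y == NEGATIVE, self._geom.negative_index, y)

    def _decode(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        return np.where(idx == self._geom.negative_index, NEGATIVE, idx)


class BinaryPatchClassifier(_RadialMLPBase):
    """Conventional particle / non-particle baseline (2 score columns;
    column 1 is the particle probability)."""

    def _n_score_classes(self) -> int:
        return 2

    def _encode(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=int)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("binary labels must be 0 or 1")
        return y

    def _decode(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=int)


class OracleDistanceClassifier:
    """Perfect distance classifier driven by the ground truth.

    Emits the one-hot score vector of the true distance label at any
    position; isolates voting/detection behaviour from learning error.
    """

    def __init__(self, truth: GroundTruth, geom: PatchGeometry = PatchGeometry()):
        self.truth = truth
        self.geom_ = geom

    def score_positions(self, image, centers: np.ndarray) -> np.ndarray:
        geom = self.geom_
        centers = np.asarray(centers)
        out = np.zeros((len(centers), geom.n_classes))
        if len(self.truth) == 0:
            out[:, geom.negative_index] = 1.0
            return out
        gt = np.round(self.truth.centers)
        d = np.hypot(
            centers[:, 0, None] - gt[None, :, 0],
            centers[:, 1, None] - gt[None, :, 1],
        ).min(axis=1)
        r = np.floor(d + 0.5).astype(int)
        idx = np.where(r <= geom.radius, r, geom.negative_index)
        out[np.arange(len(centers)), idx] = 1.0
        return out


def oracle_predict(
    truth: GroundTruth, patch_center, geom: PatchGeometry = PatchGeometry()
) -> np.ndarray:
    """One-hot class scores of the true label at ``patch_center``."""
    label = label_patch(patch_center, truth, geom)
    scores = np.zeros(geom.n_classes)
    scores[geom.negative_index if label == NEGATIVE else label] = 1.0
    return scores


# ---------------------------------------------------------------------------
# config-style facade and persistence


@dataclass(frozen=True)
class ClassifierConfig:
    architecture: str = "radial-mlp"
    n_classes: int = 27
    epochs: int = 150
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    patch_radius: int = 25

    def __post_init__(self) -> None:
        if self.n_classes not in (2, self.patch_radius + 2):
            raise ValueError(
                f"n_classes must be 2 or {self.patch_radius + 2}, got {self.n_classes}"
            )


def _estimator_for(config: ClassifierConfig) -> _RadialMLPBase:
    cls = BinaryPatchClassifier if config.n_classes == 2 else DistancePatchClassifier
    features = {"radial-mlp": "radial", "raw-mlp": "raw"}.get(config.architecture)
    if features is None:
        raise ValueError(f"unknown architecture {config.architecture!r}")
    return cls(
        patch_radius=config.patch_radius,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        features=features,
        random_state=config.seed,
    )


def train(patches: list[TrainingPatch], config: ClassifierConfig) -> _RadialMLPBase:
    """Train a classifier on labeled patches (thin functional facade)."""
    if not patches:
        raise ValueError("empty patch list")
    return _estimator_for(config).fit(patches)


def predict(model, patch: np.ndarray) -> np.ndarray:
    """Class scores of a single patch; sums to 1."""
    return np.asarray(model.predict_proba(patch))


def save_model(model: _RadialMLPBase, path) -> None:
    """Persist an estimator (joblib payload + JSON sidecar of params)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path / "model.joblib")
    sidecar = {"class": type(model).__name__, "params": model.get_params()}
    (path / "config.json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_model(path) -> _RadialMLPBase:
    return joblib.load(Path(path) / "model.joblib")
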