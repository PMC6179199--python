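"""End-to-end detector estimator: fit on annotated images, predict centers.

``VotingParticleDetector`` bundles the whole pipeline — training-patch
extraction, the patch classifier, ring voting, greedy peak read-out and
radius-matched evaluation — behind the scikit-learn estimator protocol, so
it composes with sklearn model selection.  ``method="distance"`` is the
center-voting detector; ``method="binary"`` is the conventional
particle/non-particle baseline whose probability is voted at the patch
center only.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .classifier import BinaryPatchClassifier, DistancePatchClassifier
from .detection import Detection, DetectionConfig, detect
from .evaluation import pooled_pr_curve, pr_curve
from .geometry import PatchGeometry
from .labeling import SamplingConfig, extract_training_set
from .synthetic import GroundTruth
from .voting import ScoreMap, accumulate_center_score_map, accumulate_score_map

__all__ = ["VotingParticleDetector"]


class VotingParticleDetector(BaseEstimator):
    """Particle detector trained from point-annotated images.

    Parameters mirror the pipeline stages: patch geometry, patch sampling,
    the radial-MLP classifier, the sliding-window stride, and the greedy
    detector.  ``suppression_radius`` and ``match_radius`` default to the
    patch radius.
    """

    def __init__(
        self,
        method: str = "distance",
        patch_radius: int = 25,
        stride: int = 5,
        n_positive: int | None = 5000,
        negative_ratio: float = 1.0,
        hidden_layer_sizes: tuple[int, ...] = (96, 64),
        epochs: int = 150,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        features: str = "radial",
        binary_tolerance: int = 0,
        augment_binary: bool = True,
        suppression_radius: int | None = None,
        threshold: float | None = None,
        random_state: int = 0,
    ):
        self.method = method
        self.patch_radius = patch_radius
        self.stride = stride
        self.n_positive = n_positive
        self.negative_ratio = negative_ratio
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.features = features
        self.binary_tolerance = binary_tolerance
        self.augment_binary = augment_binary
        self.suppression_radius = suppression_radius
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _geom(self) -> PatchGeometry:
        return PatchGeometry(self.patch_radius)

    def _det_config(self, threshold: float) -> DetectionConfig:
        radius = self.suppression_radius or self.patch_radius
        return DetectionConfig(suppression_radius=radius, threshold=threshold)

    def fit(self, X, y):
        """Fit on images ``X`` (list of 2-D arrays) with ground truths ``y``
        (list of :class:`GroundTruth`)."""
        if self.method not in ("distance", "binary"):
            raise ValueError(f"unknown method {self.method!r}")
        if len(X) != len(y):
            raise ValueError("need one GroundTruth per image")
        geom = self._geom()
        sampling = SamplingConfig(
            n_positive=self.n_positive,
            negative_ratio=self.negative_ratio,
            seed=self.random_state,
        )
        patches = extract_training_set(
            list(zip(X, y)),
            geom,
            sampling,
            mode=self.method,
            binary_tolerance=self.binary_tolerance,
            augment=self.augment_binary and self.method == "binary",
        )
        cls = DistancePatchClassifier if self.method == "distance" else BinaryPatchClassifier
        self.classifier_ = cls(
            patch_radius=self.patch_radius,
            hidden_layer_sizes=self.hidden_layer_sizes,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            features=self.features,
            random_state=self.random_state,
        ).fit(patches)
        self.geom_ = geom
        self.n_training_patches_ = len(patches)
        return self

    def score_map(self, image: np.ndarray) -> ScoreMap:
        """Vote the fitted classifier over one image."""
        self._check_fitted()
        if self.method == "distance":
            return accumulate_score_map(
                image, self.classifier_, self.geom_, stride=self.stride
            )
        return accumulate_center_score_map(
            image, self.classifier_, self.geom_, stride=self.stride
        )

    def predict(self, X, threshold: float | None = None):
        """Detections per image: list of lists of :class:`Detection`.

        Default threshold is 30% of each map's maximum (a mid-sweep
        operating point); pass an explicit vote-mass threshold to override.
        """
        self._check_fitted()
        single = isinstance(X, np.ndarray) and X.ndim == 2
        images = [X] if single else list(X)
        out: list[list[Detection]] = []
        for image in images:
            smap = self.score_map(image)
            t = threshold if threshold is not None else self.threshold
            if t is None:
                t = 0.3 * float(np.max(smap.values))
            out.append(detect(smap, self._det_config(t)))
        return out[0] if single else out

    def evaluate(self, X, y) -> float:
        """Maximum F-measure of the threshold sweep, pooled over images."""
        self._check_fitted()
        maps = [self.score_map(img) for img in X]
        curve = pooled_pr_curve(maps, list(y), self._det_config(0.0))
        return curve.max_f

    def score(self, X, y) -> float:  # sklearn model-selection hook
        return self.evaluate(X, y)

    def _check_fitted(self):
        if not hasattr(self, "classifier_"):
            raise RuntimeError("detector is not fitted")
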