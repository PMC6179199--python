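"""Patch classifiers: probability contracts, determinism, oracle, persistence."""

import numpy as np
import pytest

from spotvote.classifier import (
    BinaryPatchClassifier,
    ClassifierConfig,
    DistancePatchClassifier,
    OracleDistanceClassifier,
    image_position_features,
    oracle_predict,
    patch_features,
    predict,
    train,
)
from spotvote.geometry import PatchGeometry
from spotvote.labeling import NEGATIVE, TrainingPatch
from spotvote.synthetic import GroundTruth, SyntheticSpec, generate_image


def _toy_binary_set(n=200, side=51, seed=0):
    """Linearly separable patches: bright center blob (label 1) vs flat noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.1, 0.02, size=(n, side, side)).astype(np.float32)
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    r = np.arange(side) - side // 2
    blob = np.exp(-(r[:, None] ** 2 + r[None, :] ** 2) / (2 * 3.0**2))
    X[: n // 2] += 0.7 * blob
    return X, y


def test_separable_toy_set_is_fit_to_high_accuracy():
    X, y = _toy_binary_set()
    clf = BinaryPatchClassifier(epochs=100, random_state=0).fit(X, y)
    assert clf.train_accuracy_ >= 0.99
    held_out, _ = _toy_binary_set(n=20, seed=99)
    assert clf.predict(held_out[:10]).tolist() == [1] * 10  # bright-center half


def test_training_is_deterministic_under_seed():
    X, y = _toy_binary_set()
    a = BinaryPatchClassifier(epochs=30, random_state=7).fit(X, y)
    b = BinaryPatchClassifier(epochs=30, random_state=7).fit(X, y)
    assert a.loss_ == b.loss_
    np.testing.assert_array_equal(a.predict_proba(X[:5]), b.predict_proba(X[:5]))


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        DistancePatchClassifier().fit(np.zeros((0, 51, 51)), np.zeros(0))
    with pytest.raises(ValueError):
        train([], ClassifierConfig())


def test_out_of_range_labels_rejected():
    X = np.zeros((4, 51, 51))
    with pytest.raises(ValueError):
        DistancePatchClassifier().fit(X, np.array([0, 1, 26, 2]))  # 26 > radius
    with pytest.raises(ValueError):
        BinaryPatchClassifier().fit(X, np.array([0, 1, 2, 0]))


def test_patch_side_mismatch_rejected():
    X, y = _toy_binary_set(n=20)
    clf = BinaryPatchClassifier(epochs=5, random_state=0).fit(X, y)
    with pytest.raises(ValueError):
        clf.predict_proba(np.zeros((2, 31, 31)))
    with pytest.raises(ValueError):
        BinaryPatchClassifier().fit(np.zeros((4, 31, 31)), np.array([0, 1, 0, 1]))


def test_predicted_scores_are_probability_vectors():
    X, y = _toy_binary_set(n=60)
    clf = BinaryPatchClassifier(epochs=20, random_state=1).fit(X, y)
    rng = np.random.default_rng(2)
    probe = rng.uniform(0, 1, size=(16, 51, 51))
    p = clf.predict_proba(probe)
    assert (p >= 0).all()
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)
    single = predict(clf, probe[0])
    np.testing.assert_allclose(single.sum(), 1.0, atol=1e-5)


def test_distance_classifier_emits_27_columns_even_for_sparse_labels(geom):
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 1, size=(60, 51, 51)).astype(np.float32)
    y = rng.choice([0, 3, 10, NEGATIVE], size=60)
    clf = DistancePatchClassifier(epochs=5, random_state=0).fit(X, y)
    p = clf.predict_proba(X[:4])
    assert p.shape == (4, geom.n_classes)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)
    assert p[:, 1].max() == 0.0  # untrained class stays at zero probability


def test_training_patch_lists_are_accepted():
    X, y = _toy_binary_set(n=40)
    patches = [TrainingPatch(pixels=x, label=int(l)) for x, l in zip(X, y)]
    cfg = ClassifierConfig(n_classes=2, epochs=10, seed=0)
    model = train(patches, cfg)
    assert model.train_accuracy_ > 0.5


class TestOracle:
    def _truth(self):
        return GroundTruth(centers=np.array([[60.0, 60.0], [60.0, 140.0]]))

    def test_centered_patch_is_one_hot_class_zero(self, geom):
        scores = oracle_predict(self._truth(), (60, 60), geom)
        assert scores[0] == 1.0 and scores.sum() == 1.0

    def test_distance_24_is_one_hot_class_24(self, geom):
        scores = oracle_predict(self._truth(), (60, 84), geom)
        assert scores[24] == 1.0 and scores.sum() == 1.0

    def test_out_of_range_is_one_hot_negative(self, geom):
        scores = oracle_predict(self._truth(), (120, 20), geom)
        assert scores[geom.negative_index] == 1.0 and scores.sum() == 1.0

    def test_score_positions_matches_pointwise_oracle(self, geom):
        truth = self._truth()
        scorer = OracleDistanceClassifier(truth, geom)
        centers = np.array([[60, 60], [60, 84], [120, 20], [61, 61]])
        block = scorer.score_positions(None, centers)
        for row, c in zip(block, centers):
            np.testing.assert_array_equal(row, oracle_predict(truth, c, geom))


def test_image_filter_features_match_patch_features(geom):
    """Whole-image radial filters reproduce per-patch ring statistics."""
    img, _ = generate_image(SyntheticSpec(n_particles=10, seed=13))
    rng = np.random.default_rng(3)
    R = geom.radius
    centers = np.column_stack(
        [
            rng.integers(R, img.shape[0] - R, size=20),
            rng.integers(R, img.shape[1] - R, size=20),
        ]
    )
    from spotvote.labeling import extract_patch

    patches = np.stack([extract_patch(img, c, geom) for c in centers])
    direct = patch_features(patches, geom)
    filtered = image_position_features(img, centers, geom)
    np.testing.assert_allclose(filtered, direct, atol=1e-8)


def test_model_persistence_round_trip(tmp_path):
    from spotvote.classifier import load_model, save_model

    X, y = _toy_binary_set(n=40)
    clf = BinaryPatchClassifier(epochs=10, random_state=0).fit(X, y)
    save_model(clf, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    np.testing.assert_array_equal(loaded.predict_proba(X[:6]), clf.predict_proba(X[:6]))
    assert (tmp_path / "model" / "config.json").exists()
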