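"""Score patches and score-map accumulation: conservation, order, oracle peaks."""

import numpy as np
import pytest

from spotvote.classifier import OracleDistanceClassifier
from spotvote.geometry import PatchGeometry, ring_offsets, ring_sizes
from spotvote.synthetic import GroundTruth, SyntheticSpec, generate_image
from spotvote.voting import (
    accumulate_center_score_map,
    accumulate_positions,
    accumulate_score_map,
    make_score_patch,
    valid_centers,
)


def _one_hot(index, geom):
    s = np.zeros(geom.n_classes)
    s[index] = 1.0
    return s


def _random_scores(n, geom, seed):
    rng = np.random.default_rng(seed)
    s = rng.dirichlet(np.ones(geom.n_classes), size=n)
    return s


class TestScorePatch:
    def test_class_zero_mass_lands_on_the_center_pixel(self, geom):
        patch = make_score_patch(_one_hot(0, geom), geom)
        assert patch[geom.radius, geom.radius] == 1.0
        assert patch.sum() == 1.0
        assert np.count_nonzero(patch) == 1

    def test_negative_class_casts_no_votes(self, geom):
        patch = make_score_patch(_one_hot(geom.negative_index, geom), geom)
        assert not patch.any()

    def test_uniform_positive_scores_split_per_ring(self, geom):
        scores = np.full(geom.n_classes, 1 / 26)
        scores[geom.negative_index] = 0.0
        patch = make_score_patch(scores, geom)
        np.testing.assert_allclose(patch.sum(), 1.0, atol=1e-12)
        sizes = ring_sizes(geom)
        for r in (0, 1, 13, 25):
            ring = list(ring_offsets(r, geom))
            vals = [patch[geom.radius + dr, geom.radius + dc] for dr, dc in ring]
            np.testing.assert_allclose(sum(vals), 1 / 26, atol=1e-12)
            np.testing.assert_allclose(vals, 1 / (26 * sizes[r]), atol=1e-15)

    def test_copy_mode_assigns_full_score_per_ring_pixel(self, geom):
        patch = make_score_patch(_one_hot(5, geom), geom, mode="copy")
        for dr, dc in ring_offsets(5, geom):
            assert patch[geom.radius + dr, geom.radius + dc] == 1.0

    def test_mass_conservation_on_random_scores(self, geom):
        for i, scores in enumerate(_random_scores(25, geom, seed=1)):
            patch = make_score_patch(scores, geom)
            positive_mass = scores[: geom.radius + 1].sum()
            np.testing.assert_allclose(patch.sum(), positive_mass, atol=1e-6)

    def test_invalid_scores_rejected(self, geom):
        with pytest.raises(ValueError):
            make_score_patch(np.ones(5), geom)
        bad = _one_hot(0, geom)
        bad[3] = -0.1
        with pytest.raises(ValueError):
            make_score_patch(bad, geom)


class _FixedScorer:
    """Deterministic pseudo-classifier for accumulation tests."""

    def __init__(self, geom, seed=0):
        self.geom = geom
        self.seed = seed

    def score_positions(self, image, centers):
        rng = np.random.default_rng(self.seed)
        # scores depend only on position so both engines see the same input
        raw = rng.dirichlet(np.ones(self.geom.n_classes), size=10_000)
        idx = (np.asarray(centers)[:, 0] * 31 + np.asarray(centers)[:, 1]) % 10_000
        return raw[idx]


class TestAccumulation:
    def test_single_position_one_hot_gives_single_pixel(self, geom):
        class CenterScorer:
            def score_positions(self, image, centers):
                return np.tile(_one_hot(0, geom), (len(centers), 1))

        img = np.zeros((51, 51))  # exactly one valid patch position
        smap = accumulate_score_map(img, CenterScorer(), geom, stride=1, engine="loop")
        assert np.count_nonzero(smap.values) == 1
        assert smap.values[25, 25] == 1.0

    @pytest.mark.parametrize("stride", [1, 5])
    def test_total_mass_conserved(self, geom, stride):
        img = np.zeros((100, 90))
        scorer = _FixedScorer(geom, seed=3)
        centers = valid_centers(img.shape, geom, stride)
        scores = scorer.score_positions(img, centers)
        expected = scores[:, : geom.radius + 1].sum()
        for engine in ("loop", "fft"):
            smap = accumulate_score_map(img, scorer, geom, stride, engine=engine)
            np.testing.assert_allclose(smap.values.sum(), expected, rtol=1e-9)
            assert smap.values.min() >= 0.0

    def test_engines_agree(self, geom):
        img = np.zeros((80, 100))
        scorer = _FixedScorer(geom, seed=4)
        a = accumulate_score_map(img, scorer, geom, stride=3, engine="loop")
        b = accumulate_score_map(img, scorer, geom, stride=3, engine="fft")
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_accumulation_order_is_irrelevant(self, geom):
        img = np.zeros((80, 80))
        scorer = _FixedScorer(geom, seed=5)
        centers = valid_centers(img.shape, geom, 4)
        scores = scorer.score_positions(img, centers)
        fwd = accumulate_positions(img.shape, centers, scores, geom)
        perm = np.random.default_rng(0).permutation(len(centers))
        rev = accumulate_positions(img.shape, centers[perm], scores[perm], geom)
        np.testing.assert_allclose(fwd, rev, atol=1e-12)

    def test_stride5_votes_are_a_subset_of_stride1_votes(self, geom):
        """Each stride-5 position contributes identically in both scans."""
        img = np.zeros((76, 76))
        scorer = _FixedScorer(geom, seed=6)
        c1 = valid_centers(img.shape, geom, 1)
        c5 = valid_centers(img.shape, geom, 5)
        assert {tuple(c) for c in c5} <= {tuple(c) for c in c1}
        s1 = scorer.score_positions(img, c1)
        s5 = scorer.score_positions(img, c5)
        lookup = {tuple(c): s for c, s in zip(c1, s1)}
        for c, s in zip(c5, s5):
            np.testing.assert_array_equal(lookup[tuple(c)], s)
        smap5 = accumulate_score_map(img, scorer, geom, stride=5, engine="loop")
        np.testing.assert_allclose(
            smap5.values, accumulate_positions(img.shape, c5, s5, geom), atol=1e-12
        )

    def test_oracle_votes_peak_exactly_at_an_isolated_center(self, geom):
        truth = GroundTruth(centers=np.array([[60.0, 64.0]]))
        img = np.zeros((128, 128))
        scorer = OracleDistanceClassifier(truth, geom)
        smap = accumulate_score_map(img, scorer, geom, stride=1)
        r, c = np.unravel_index(np.argmax(smap.values), smap.values.shape)
        assert (r, c) == (60, 64)
        # strict local maximum: all 8 neighbours carry strictly less mass
        peak = smap.values[60, 64]
        neigh = smap.values[59:62, 63:66].copy()
        neigh[1, 1] = -np.inf
        assert (neigh < peak).all()

    def test_oracle_separated_particles_are_all_strict_maxima(self, geom):
        img, truth = generate_image(
            SyntheticSpec(n_particles=5, min_separation=55, cluster_fraction=0, seed=21)
        )
        smap = accumulate_score_map(img, OracleDistanceClassifier(truth, geom), geom, 1)
        for cr, cc in np.round(truth.centers).astype(int):
            peak = smap.values[cr, cc]
            window = smap.values[cr - 1 : cr + 2, cc - 1 : cc + 2].copy()
            window[1, 1] = -np.inf
            assert (window < peak).all()

    def test_image_smaller_than_patch_rejected(self, geom):
        with pytest.raises(ValueError):
            accumulate_score_map(np.zeros((50, 60)), _FixedScorer(geom), geom)

    def test_center_voting_map_for_binary_baseline(self, geom):
        class P:
            def score_positions(self, image, centers):
                out = np.zeros((len(centers), 2))
                out[:, 1] = 0.5
                out[:, 0] = 0.5
                return out

        img = np.zeros((61, 61))
        smap = accumulate_center_score_map(img, P(), geom, stride=5)
        centers = valid_centers(img.shape, geom, 5)
        assert np.count_nonzero(smap.values) == len(centers)
        np.testing.assert_allclose(smap.values.sum(), 0.5 * len(centers))
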