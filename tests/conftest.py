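import numpy as np
import pytest

from spotvote import (
    OracleDistanceClassifier,
    PatchGeometry,
    SyntheticSpec,
    accumulate_score_map,
    generate_image,
)


@pytest.fixture(scope="session")
def geom():
    return PatchGeometry()


@pytest.fixture(scope="session")
def sparse_scene():
    """Synthetic image whose particles are pairwise > 50 px apart, so every
    one is detectable under the 25 px suppression radius."""
    spec = SyntheticSpec(n_particles=7, min_separation=55.0, cluster_fraction=0.0, seed=11)
    return generate_image(spec)


@pytest.fixture(scope="session")
def oracle_map(sparse_scene, geom):
    image, truth = sparse_scene
    scorer = OracleDistanceClassifier(truth, geom)
    return accumulate_score_map(image, scorer, geom, stride=1), truth
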