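import numpy as np
import pytest

from dpga.graph import CohortTable, DiseaseVocabulary, build_graph
from dpga.simulate import generate_toy_graph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_vocab():
    return DiseaseVocabulary(("I10", "E11", "J44", "I25", "N18"))


@pytest.fixture
def toy_graph():
    """A small connected co-diagnosis graph for attention tests."""
    return generate_toy_graph(6, 6, seed=7)


@pytest.fixture
def random_cohort(rng):
    X = (rng.random((12, 8)) < 0.5).astype(np.int8)
    X[0, 0] = X[1, 0] = 1          # guarantee at least one edge
    y = rng.integers(0, 2, 12)
    vocab = DiseaseVocabulary(tuple(f"D{i}" for i in range(8)))
    return CohortTable(X=X, y=y, vocabulary=vocab)


@pytest.fixture
def random_graph(random_cohort):
    return build_graph(random_cohort, min_shared=1)
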