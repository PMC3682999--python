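import numpy as np
import pytest

from ordsim import WordSet, geography_fixtures
from ordsim.synthetic import GeneratorSpec, synthetic_semantic_matrix


@pytest.fixture(scope="session")
def fx():
    """Worked-example vectors and word sets for the geography experiment."""
    return geography_fixtures()


@pytest.fixture(scope="session")
def words(fx):
    return fx.words


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-scale generator: 5 geography words, 20 trials each, 6
    channels — fast enough for repeated classification in tests."""
    w = WordSet(["London", "Paris", "north", "south", "Germany"])
    return GeneratorSpec(
        words=w,
        trials_per_word=(20,) * 5,
        channels=6,
        epoch_len=60,
        snr=1.0,
        target_sim=synthetic_semantic_matrix(w, seed=5),
        seed=11,
    )


def random_similarity(words: WordSet, rng: np.random.Generator):
    """Random symmetric similarity matrix with unit diagonal."""
    n = len(words)
    a = rng.uniform(0, 1, size=(n, n))
    s = (a + a.T) / 2
    np.fill_diagonal(s, 1.0)
    return s
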