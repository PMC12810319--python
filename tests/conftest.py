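"""Shared fixtures.

The session-scoped trained scorer is the expensive fixture (a 30-epoch
training run on a 2000-image synthetic corpus, a few minutes on one core);
every test that needs a converged model shares it.
"""

import pytest

from sift2d.scorer import desk_scorer_config, train_scorer
from sift2d.synthetic_data import make_labeled_corpus


@pytest.fixture(scope="session")
def corpus_seed7():
    """The standard training corpus: n=2000, uniform grade mixture, seed 7."""
    return make_labeled_corpus(n=2000, seed=7)


@pytest.fixture(scope="session")
def trained_model(corpus_seed7):
    """Scorer trained for 30 epochs on the standard corpus (desk-scale config)."""
    return train_scorer(corpus_seed7, desk_scorer_config(seed=7, epochs=30))


@pytest.fixture(scope="session")
def cross_seed_corpus():
    """Evaluation corpus from a different generator seed than training."""
    return make_labeled_corpus(n=500, seed=123)
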