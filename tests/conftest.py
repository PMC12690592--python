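import numpy as np
import pytest

from clmrl import toy
from clmrl.config import RunConfig
from clmrl.policy import GRUPolicy
from clmrl.runner import build_prior
from clmrl.vocab import Vocabulary


@pytest.fixture(scope="session")
def corpus():
    return toy.make_corpus(123, 300)


@pytest.fixture(scope="session")
def vocab(corpus):
    return Vocabulary.from_corpus(corpus)


@pytest.fixture(scope="session")
def tiny_policy(vocab):
    """Small random (untrained) policy for fast mechanical tests."""
    return GRUPolicy(vocab, embedding_size=8, hidden_size=12, seed=5)


@pytest.fixture(scope="session")
def toy_run_config():
    """Study conditions for the scaled-down learning checks."""
    return RunConfig.model_validate(
        {
            "seed": 0,
            "budget": 5000,
            "batch_size": 50,
            "policy": {"max_len": 48},
        }
    )


@pytest.fixture(scope="session")
def trained_prior(toy_run_config):
    """One pretrained toy prior shared by all learning tests (built once)."""
    return build_prior(toy_run_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
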