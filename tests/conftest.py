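import numpy as np
import pytest
from hypothesis import settings

from molseal.generator import MockPolicy, pretrain
from molseal.oracles import generate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# Fixture-prior study conditions: a 20 000-molecule grammar corpus and a
# compact single-layer GRU trained to ~90% sample validity.
PRIOR_CORPUS_N = 20_000
PRIOR_CORPUS_SEED = 101
PRIOR_KW = dict(epochs=18, embed_dim=64, hidden_dim=160, n_layers=1,
                lr=2e-3, max_len=100, seed=7)


@pytest.fixture(scope="session")
def corpus_small():
    return generate_corpus(300, seed=11)


@pytest.fixture(scope="session")
def corpus_medium():
    return generate_corpus(2000, seed=23)


@pytest.fixture()
def mock_prior(corpus_small):
    return MockPolicy(corpus_small, np.zeros(len(corpus_small)), role="prior")


@pytest.fixture(scope="session")
def fixture_corpus():
    return generate_corpus(PRIOR_CORPUS_N, seed=PRIOR_CORPUS_SEED)


@pytest.fixture(scope="session")
def fixture_prior(fixture_corpus):
    model, history = pretrain(fixture_corpus, **PRIOR_KW)
    # training must have moved the held-out NLL; guards against a silent no-op
    assert history["holdout_nll_per_token"][-1] < history["holdout_nll_per_token"][0]
    return model


@pytest.fixture(scope="session")
def tiny_prior(corpus_small):
    model, _ = pretrain(corpus_small, epochs=3, embed_dim=32, hidden_dim=48,
                        n_layers=1, lr=2e-3, max_len=100, seed=3)
    return model
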