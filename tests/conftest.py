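import numpy as np
import pytest

from notelink.embedding import EmbeddingCache, HashingEmbeddingProvider
from notelink.fixtures import (
    FixtureSpec,
    make_abbrev_corpus,
    make_annotated_docs,
    make_cohort,
    make_terminology,
)


@pytest.fixture(scope="session")
def provider():
    return HashingEmbeddingProvider()


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def term_fixture(spec):
    return make_terminology(spec)


@pytest.fixture(scope="session")
def embedded_term(term_fixture, provider):
    if term_fixture.index.embedding_index is None:
        term_fixture.index.build_description_index(EmbeddingCache(provider))
    return term_fixture


@pytest.fixture(scope="session")
def docs_fixture(spec, term_fixture):
    return make_annotated_docs(spec, term_fixture)


@pytest.fixture(scope="session")
def abbrev_fixture(spec):
    return make_abbrev_corpus(spec)


@pytest.fixture(scope="session")
def cohort_fixture(spec, term_fixture):
    return make_cohort(spec, term_fixture)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
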