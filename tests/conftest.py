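import pytest

from varlit.corpus import index_collection
from varlit.fixtures import default_spec, generate_corpus


@pytest.fixture(scope="session")
def fixture_corpus():
    """The default synthetic study corpus (three planted oncogene triplets)."""
    return generate_corpus(default_spec(seed=0))


@pytest.fixture(scope="session")
def fixture_index(fixture_corpus):
    return index_collection(fixture_corpus.documents)
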