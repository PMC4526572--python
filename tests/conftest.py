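import pytest

from crypticpts.motif import SEARCH_GRAMMAR, UNION_GRAMMAR
from crypticpts.synthetic import make_example_fixtures


@pytest.fixture(scope="session")
def examples():
    """The worked-example gene contexts."""
    return make_example_fixtures()


@pytest.fixture(scope="session")
def union():
    return UNION_GRAMMAR


@pytest.fixture(scope="session")
def search():
    return SEARCH_GRAMMAR
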