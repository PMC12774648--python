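import pytest

from structannot import FixtureSpec, SearchParams, generate_database


@pytest.fixture(scope="session")
def params():
    """Default search parameters (bundled BLOSUM62 + synthetic 3Di matrix)."""
    return SearchParams()


@pytest.fixture(scope="session")
def small_db():
    """A small labelled database shared across tests."""
    spec = FixtureSpec(seed=101, db_size=30)
    records, labels = generate_database(spec)
    return spec, records, labels
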