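import pytest

from metasheet import fixtures


@pytest.fixture(scope="session")
def showcase_session():
    """The showcase-shaped synthetic sheet: 6 diets x 5 replicates, mouse,
    bulk RNA-seq, one count matrix.  Session-scoped; never mutate."""
    return fixtures.generate_sheet(1)


@pytest.fixture()
def showcase(showcase_session):
    sheet, vocab, registry = showcase_session
    return sheet.model_copy(deep=True), vocab, registry


@pytest.fixture(scope="session")
def base_vocab():
    return fixtures.base_vocabulary()


@pytest.fixture(scope="session")
def base_registry():
    return fixtures.base_registry()
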