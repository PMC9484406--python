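import pytest

from eoadtriage import fixtures, pipeline


@pytest.fixture(scope="session")
def tables():
    return fixtures.load_fixture_tables()


@pytest.fixture(scope="session")
def panels():
    return fixtures.load_panels()


@pytest.fixture(scope="session")
def cohort(tables):
    return fixtures.fixture_cohort(tables)


@pytest.fixture(scope="session")
def published(tables):
    """Pipeline result on the packaged published tables."""
    return pipeline.run_published_fixtures()
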