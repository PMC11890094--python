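import pytest
from hypothesis import HealthCheck, settings

from geinfo import (
    CorpusSpec,
    ErrorProfile,
    MockBackend,
    generate_corpus,
    get_template,
    run_extraction,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def corpus():
    """A mid-sized synthetic corpus shared across tests."""
    return generate_corpus(CorpusSpec(seed=11, n_articles=60))


@pytest.fixture(scope="session")
def round2():
    return get_template("round2")


@pytest.fixture(scope="session")
def round1():
    return get_template("round1")


@pytest.fixture(scope="session")
def zero_error_records(corpus, round2):
    """Extraction records from the error-free mock backend."""
    backend = MockBackend(corpus, ErrorProfile.zero())
    return run_extraction(corpus.articles, corpus.contexts(), round2, backend)
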