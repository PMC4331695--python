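import pytest
from hypothesis import settings

from chemtagger.engine import ResourceSet
from chemtagger.fixtures import builtin_resources
from chemtagger.postprocess import WordLists

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def resources() -> ResourceSet:
    return builtin_resources()


@pytest.fixture(scope="session")
def wordlists() -> WordLists:
    return WordLists()
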