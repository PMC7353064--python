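import pytest

from secretalk.core import CriteriaConfig
from secretalk.fixtures import build_paper_fixtures
from secretalk.synthetic import mini_ontology


@pytest.fixture(scope="session")
def config():
    return CriteriaConfig()


@pytest.fixture(scope="session")
def dag():
    return mini_ontology()


@pytest.fixture(scope="session")
def paper_fixtures():
    return build_paper_fixtures()


@pytest.fixture(scope="session")
def tables_fixture(paper_fixtures):
    return paper_fixtures["tables_1_2"]
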