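import pytest
from hypothesis import settings

from metexpand import fixtures as fx

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from metexpand.rules import classify_network


@pytest.fixture(scope="session")
def pathway():
    return fx.noscapine_pathway()


@pytest.fixture(scope="session")
def rules():
    return fx.mini_rules()


@pytest.fixture(scope="session")
def rules_by_id(rules):
    return {r.rule_id: r for r in rules}


@pytest.fixture(scope="session")
def catalogs():
    return fx.mini_catalogs()


@pytest.fixture(scope="session")
def reference_db():
    return list(fx.mini_reference_db())


@pytest.fixture(scope="session")
def annotations():
    return fx.annotation_table()


@pytest.fixture(scope="session")
def names():
    return fx.compound_names()


@pytest.fixture(scope="session")
def network(pathway, reference_db):
    """The fully expanded (4 generations) and classified fixture network."""
    net = fx.expanded_network(4)
    return classify_network(net, reference_db, pathway)


def key(name: str) -> str:
    return fx.key_of(name)


@pytest.fixture(scope="session")
def key_of():
    return key
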