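import pytest

from overrep.annotation import GeneUniverse, GmtRecord, build_store
from overrep.fixtures import FixtureSpec, generate_fixture


@pytest.fixture
def universe10():
    """Ten genes g1..g10, the hand-checkable background."""
    return GeneUniverse.from_genes([f"g{i}" for i in range(1, 11)])


@pytest.fixture
def store10(universe10):
    """Three overlapping terms over the 10-gene universe."""
    records = [
        GmtRecord("T1", "first term", ("g1", "g2", "g3", "g4")),
        GmtRecord("T2", "second term", ("g3", "g4", "g5", "g6", "g7")),
        GmtRecord("T3", "third term", ("g1", "g2")),
    ]
    store, _ = build_store(records, universe10, source="GO:BP")
    return store


@pytest.fixture(scope="session")
def fixture300():
    """A mid-size synthetic world shared by slower tests."""
    return generate_fixture(FixtureSpec(N=300, T=20, size_range=(8, 60), seed=11))
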