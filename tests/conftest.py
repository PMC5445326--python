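import pytest

from rgnn import SSNDocument, SequenceNode
from rgnn.synth import SyntheticSpec, generate


@pytest.fixture
def toy_ssn() -> SSNDocument:
    """The 6-node hand-scanned network: K4 at score 100 plus two pendants.

    Exhaustive scan: Th=60 -> (Nn=6, SE=8), Th=61 -> (5, 7), Th=71 -> (4, 6),
    Th=101 -> (0, 0); hence A-Th = 61 (first Nsv rise) and S-Th = 60 (first
    step losing relatively more connected nodes than edges).
    """
    ssn = SSNDocument()
    for u, v in [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]:
        ssn.add_edge(u, v, 100.0)
    ssn.add_edge("a", "e", 60.0)
    ssn.add_edge("b", "f", 70.0)
    return ssn


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """A quick-to-generate synthetic family with subspecies duplicates."""
    return SyntheticSpec(
        n_clusters=2,
        sequences_per_cluster=25,
        subspecies_rate=0.3,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_spec):
    return generate(small_spec)


@pytest.fixture
def rich_node_ssn() -> SSNDocument:
    """Two rep-nodes plus a plain node, with taxids and metadata."""
    ssn = SSNDocument(metadata={"family": "demo"})
    ssn.add_node(SequenceNode("R1", ["A1", "A2", "A3"], [562, 83333, 632]))
    ssn.add_node(SequenceNode("R2", ["B1", "B2"], [1280, 0]))
    ssn.add_node(SequenceNode("P1", ["C1"], [1423]))
    ssn.add_edge("R1", "R2", 87.5)
    ssn.add_edge("R2", "P1", 42.25)
    return ssn
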