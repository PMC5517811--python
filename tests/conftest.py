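import pytest

from pacscore import (
    AnnotationConfidenceModel,
    AnnotationMap,
    GeneRecord,
    GenomeTable,
    OntologyGraph,
    SimilarityScorer,
    SimulationConfig,
    SyntheticStudy,
)


def make_graph(edges, namespaces):
    """Build an OntologyGraph from (child, parent) pairs and a ns mapping."""
    return OntologyGraph(edges, namespaces)


@pytest.fixture
def diamond_graph():
    """root -> P, root -> Q, P and Q -> A (A has two parents)."""
    ns = {t: "BP" for t in ("root", "P", "Q", "A")}
    return make_graph([("P", "root"), ("Q", "root"), ("A", "P"), ("A", "Q")], ns)


@pytest.fixture
def chain_graph():
    """root -> X -> Y linear chain."""
    ns = {t: "BP" for t in ("root", "X", "Y")}
    return make_graph([("X", "root"), ("Y", "X")], ns)


@pytest.fixture
def shrub_graph():
    """root with children P (itself parent of A and B) used for Jaccard sums."""
    ns = {t: "BP" for t in ("root", "P", "A", "B")}
    return make_graph([("P", "root"), ("A", "P"), ("B", "P")], ns)


@pytest.fixture
def linear_genome():
    """Nine genes on one linear replicon, alternating strands in blocks."""
    strands = "+++---+++"
    recs = [
        GeneRecord(f"g{i}", "chr", i, strands[i], f"op{i // 3}")
        for i in range(9)
    ]
    return GenomeTable(recs, "linear")


@pytest.fixture
def circular_genome():
    recs = [GeneRecord(f"g{i}", "chr", i, "+", None) for i in range(8)]
    return GenomeTable(recs, "circular")


@pytest.fixture(scope="session")
def small_study():
    """A 400-gene synthetic study for module-level pipeline tests."""
    return SyntheticStudy(SimulationConfig(seed=7, n_genes=400))


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions: 2000 genes, rho 0.8, seed 0."""
    return SyntheticStudy(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_fit(default_study):
    s = default_study
    model = AnnotationConfidenceModel(s.genome, s.annotations, s.graph)
    return model.fit(seed=0)
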