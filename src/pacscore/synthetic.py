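"""Synthetic ontologies, genomes and annotations for self-contained studies.

The generator emulates the one statistical property the method reads from
real bacterial genomes: genes that are chromosomal neighbors — and above
all operon mates — tend to share function.  Each namespace gets a random
rooted is-a DAG; a circular gene order is partitioned into operons
(geometric sizes, one strand per operon); each operon is assigned a
"theme" term per namespace, and member genes draw their annotations from
the theme's sub-DAG with probability rho * (1 - noise), otherwise
uniformly from the namespace.  All randomness flows from one seed through
named substreams so the ontology, genome and annotations can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationMap, GeneRecord, GenomeTable
from .ontology import NAMESPACES, OntologyGraph

_STREAMS = {"ontology": 1, "genome": 2, "annotation": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults describe a moderately well-annotated bacterial chromosome:
    2000 genes in operons of mean size 3, 70% of genes GO-annotated per
    namespace, strong within-operon functional coherence (rho = 0.8) with
    a 10% uniform-noise term rate, and 60-term namespaces deep enough for
    a graded similarity signal.
    """

    seed: int = 0
    n_terms: int = 60  # per namespace, including the root
    max_parents: int = 2
    n_genes: int = 2000
    operon_mean_size: float = 3.0
    frac_annotated: float = 0.7  # per namespace
    rho: float = 0.8  # within-operon sharing probability
    noise: float = 0.1  # uniform-random term rate
    terms_per_gene_mean: float = 2.0
    replicon_id: str = "chr"

    def __post_init__(self) -> None:
        for name in ("frac_annotated", "rho", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_terms < 2:
            raise ValueError("need at least a root and one child per namespace")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def simulate_ontology(config: SimulationConfig) -> OntologyGraph:
    """A random rooted DAG per namespace.

    Terms are added in order; each non-root term picks 1..max_parents
    parents among earlier terms, which guarantees acyclicity and a path
    to the root.
    """
    rng = _rng(config.seed, "ontology")
    namespace_of: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    for k, ns in enumerate(NAMESPACES):
        terms = [f"SYN:{k}{i:06d}" for i in range(config.n_terms)]
        for term in terms:
            namespace_of[term] = ns
        for i in range(1, config.n_terms):
            n_parents = int(rng.integers(1, config.max_parents + 1))
            n_parents = min(n_parents, i)
            parents = rng.choice(i, size=n_parents, replace=False)
            for p in parents:
                edges.append((terms[i], terms[int(p)]))
    return OntologyGraph(edges, namespace_of)


def _operon_sizes(rng: np.random.Generator, n_genes: int, mean: float) -> list[int]:
    sizes = []
    total = 0
    p = 1.0 / max(mean, 1.0)
    while total < n_genes:
        size = int(min(rng.geometric(p), n_genes - total))
        sizes.append(size)
        total += size
    return sizes


def simulate_genome_and_annotations(
    config: SimulationConfig, graph: OntologyGraph
) -> tuple[GenomeTable, AnnotationMap]:
    """A circular operon-structured genome with theme-correlated annotations."""
    genome_rng = _rng(config.seed, "genome")
    ann_rng = _rng(config.seed, "annotation")

    sizes = _operon_sizes(genome_rng, config.n_genes, config.operon_mean_size)
    records: list[GeneRecord] = []
    rank = 0
    operon_of_gene: dict[str, str] = {}
    for op_idx, size in enumerate(sizes):
        strand = "+" if genome_rng.random() < 0.5 else "-"
        operon_id = f"op{op_idx:05d}"
        for _ in range(size):
            gene_id = f"g{rank:05d}"
            records.append(
                GeneRecord(gene_id, config.replicon_id, rank, strand, operon_id)
            )
            operon_of_gene[gene_id] = operon_id
            rank += 1
    genome = GenomeTable(records, "circular")

    # per-namespace term universe and per-operon theme terms
    non_root = {
        ns: sorted(t for t in graph.terms if graph.namespace_of[t] == ns
                   and not graph.is_root(t))
        for ns in NAMESPACES
    }
    themes: dict[tuple[str, str], str] = {}
    for op_idx in range(len(sizes)):
        for ns in NAMESPACES:
            pool = non_root[ns]
            themes[(f"op{op_idx:05d}", ns)] = pool[int(ann_rng.integers(len(pool)))]
    sub_dag = {
        theme: sorted(graph.descendants(theme)) for theme in set(themes.values())
    }

    annotations = AnnotationMap()
    p_theme = config.rho * (1.0 - config.noise)
    for rec in records:
        for ns in NAMESPACES:
            if ann_rng.random() >= config.frac_annotated:
                continue
            n_terms = 1 + int(ann_rng.poisson(max(config.terms_per_gene_mean - 1, 0)))
            theme = themes[(rec.operon_id, ns)]
            near = sub_dag[theme]
            for _ in range(n_terms):
                if ann_rng.random() < p_theme:
                    term = near[int(ann_rng.integers(len(near)))]
                else:
                    pool = non_root[ns]
                    term = pool[int(ann_rng.integers(len(pool)))]
                annotations.add(rec.gene_id, ns, term)
    return genome, annotations


@dataclass
class SyntheticStudy:
    """One fully generated study: ontology, genome and true annotations."""

    config: SimulationConfig
    graph: OntologyGraph = field(init=False)
    genome: GenomeTable = field(init=False)
    annotations: AnnotationMap = field(init=False)

    def __post_init__(self) -> None:
        self.graph = simulate_ontology(self.config)
        self.genome, self.annotations = simulate_genome_and_annotations(
            self.config, self.graph
        )

    def write(self, obo_path: str, gaf_path: str, genes_path: str) -> None:
        """Emit standard OBO / GAF / gene-table files for the readers."""
        self.graph.to_obo(obo_path)
        self.annotations.to_gaf(gaf_path)
        self.genome.to_tsv(genes_path)
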