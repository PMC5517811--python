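"""Gene Ontology handling: OBO parsing, ancestor closures, term similarity.

The ontology is reduced to its ``is_a`` subclass edges, which form a rooted
DAG per namespace (biological process, molecular function, cellular
component).  Term-level similarity is the Jaccard index of the two terms'
ancestor sets, where an ancestor set contains the term itself and every
term reachable upward through ``is_a`` edges, excluding the namespace root
(the root carries no functional information).

Abundant, uninformative terms (e.g. a generic "membrane" component) can be
filtered by their frequency in a background protein pool; filtered terms
are removed both from direct annotations and from ancestor sets during
similarity scoring, so an abundant ancestor cannot re-introduce spurious
overlap between unrelated terms.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: canonical namespace codes, keyed by the OBO namespace strings
NAMESPACES = ("BP", "MF", "CC")
_OBO_NAMESPACE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_NAMESPACE_OBO = {v: k for k, v in _OBO_NAMESPACE.items()}


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or invalid term queries."""


class UnknownTermError(KeyError):
    """Raised when a term (after alt_id resolution) is absent from the graph."""


class OntologyGraph:
    """A rooted is-a DAG per GO namespace.

    Parameters
    ----------
    is_a_edges
        Iterable of ``(child, parent)`` pairs.
    namespace_of
        Mapping term -> namespace code in ``{"BP", "MF", "CC"}``.
    alt_id_map
        Optional mapping of alias identifiers to primary identifiers.
    """

    def __init__(
        self,
        is_a_edges: Iterable[tuple[str, str]],
        namespace_of: Mapping[str, str],
        alt_id_map: Mapping[str, str] | None = None,
    ) -> None:
        self.namespace_of: dict[str, str] = dict(namespace_of)
        self.alt_id_map: dict[str, str] = dict(alt_id_map or {})
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace_of)
        for child, parent in is_a_edges:
            if child not in self.namespace_of or parent not in self.namespace_of:
                raise OntologyError(f"edge ({child}, {parent}) references unknown term")
            if self.namespace_of[child] != self.namespace_of[parent]:
                raise OntologyError(
                    f"is_a edge crosses namespaces: {child} -> {parent}"
                )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("cycle detected in is_a graph")
        self._graph = g
        # roots are detected structurally: terms with no is_a parent
        self.roots: dict[str, str] = {}
        for term in g.nodes:
            if g.out_degree(term) == 0:
                ns = self.namespace_of[term]
                if ns in self.roots:
                    raise OntologyError(
                        f"multiple roots in namespace {ns}: "
                        f"{self.roots[ns]}, {term}"
                    )
                self.roots[ns] = term
        self._closure_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ---------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def is_root(self, term: str) -> bool:
        return self.roots.get(self.namespace_of[term]) == term

    def parents(self, term: str) -> set[str]:
        return set(self._graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._graph.predecessors(term))

    def resolve(self, term: str) -> str:
        """Map an alias (alt_id) to its primary identifier.

        Raises
        ------
        UnknownTermError
            If the identifier is neither a primary term nor a known alias.
        """
        if term in self._graph:
            return term
        if term in self.alt_id_map:
            return self.alt_id_map[term]
        raise UnknownTermError(term)

    def descendants(self, term: str) -> frozenset[str]:
        """The term plus every more-specific term below it (child direction)."""
        term = self.resolve(term)
        return frozenset(nx.ancestors(self._graph, term)) | {term}

    # -- ancestor closures and similarity --------------------------------

    def ancestor_closure(self, term: str) -> frozenset[str]:
        """The term plus all is-a ancestors, excluding the namespace root.

        The closure of a root is empty.  Results are memoized.
        """
        term = self.resolve(term)
        cached = self._closure_cache.get(term)
        if cached is not None:
            return cached
        # edges point child -> parent, so ancestors are nx descendants
        members = set(nx.descendants(self._graph, term))
        members.add(term)
        members.discard(self.roots[self.namespace_of[term]])
        closure = frozenset(members)
        self._closure_cache[term] = closure
        return closure

    def similarity(self, go1: str, go2: str) -> float:
        """Jaccard index of the two terms' ancestor closures."""
        return go_similarity(self, go1, go2)

    def to_obo(self, path: str) -> None:
        """Write the graph as a minimal OBO 1.2 flat file."""
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n\n")
            for term in sorted(self._graph.nodes):
                fh.write("[Term]\n")
                fh.write(f"id: {term}\n")
                fh.write(f"name: {term}\n")
                fh.write(f"namespace: {_NAMESPACE_OBO[self.namespace_of[term]]}\n")
                for alias, primary in sorted(self.alt_id_map.items()):
                    if primary == term:
                        fh.write(f"alt_id: {alias}\n")
                for parent in sorted(self._graph.successors(term)):
                    fh.write(f"is_a: {parent}\n")
                fh.write("\n")


def parse_obo(path: str) -> OntologyGraph:
    """Parse an OBO 1.2 file, keeping only ``is_a`` edges.

    Obsolete terms are dropped, ``alt_id`` aliases are recorded, and terms
    lacking a namespace are rejected with a warning.  One root per
    namespace (a term with no is_a parent) is identified structurally.
    """
    raw = obonet.read_obo(path, ignore_obsolete=True)
    namespace_of: dict[str, str] = {}
    alt_id_map: dict[str, str] = {}
    for term, data in raw.nodes(data=True):
        ns = data.get("namespace")
        if ns not in _OBO_NAMESPACE:
            logger.warning("term %s has no recognised namespace; dropped", term)
            continue
        namespace_of[term] = _OBO_NAMESPACE[ns]
        for alias in data.get("alt_id", []):
            alt_id_map[alias] = term
    edges = [
        (child, parent)
        for child, parent, key in raw.edges(keys=True)
        if key == "is_a" and child in namespace_of and parent in namespace_of
    ]
    return OntologyGraph(edges, namespace_of, alt_id_map)


def go_similarity(
    graph: OntologyGraph,
    go1: str,
    go2: str,
    excluded: frozenset[str] | None = None,
) -> float:
    """Ancestor-set Jaccard similarity between two non-root terms.

    ``excluded`` terms (typically abundant background terms) are removed
    from both closures before the Jaccard index is taken.  Two terms whose
    only shared ancestor is the root score 0; identical closures score 1.
    """
    go1 = graph.resolve(go1)
    go2 = graph.resolve(go2)
    if graph.is_root(go1) or graph.is_root(go2):
        raise OntologyError("root terms carry no information")
    s1 = graph.ancestor_closure(go1)
    s2 = graph.ancestor_closure(go2)
    if excluded:
        s1 = s1 - excluded
        s2 = s2 - excluded
    union = len(s1 | s2)
    if union == 0:
        return 0.0
    return len(s1 & s2) / union


class SimilarityScorer:
    """Caching term-pair similarity scorer with abundant-term exclusion.

    Instances hold per-ontology caches of (pruned) ancestor closures and
    pairwise similarities; profile building funnels every term comparison
    through one scorer so repeated pairs cost a dictionary lookup.
    """

    def __init__(
        self, graph: OntologyGraph, excluded: Iterable[str] = ()
    ) -> None:
        self.graph = graph
        self.excluded = frozenset(graph.resolve(t) for t in excluded)
        self._closures: dict[str, frozenset[str]] = {}
        self._pairs: dict[tuple[str, str], float] = {}

    def closure(self, term: str) -> frozenset[str]:
        c = self._closures.get(term)
        if c is None:
            c = self.graph.ancestor_closure(term) - self.excluded
            self._closures[term] = c
        return c

    def similarity(self, go1: str, go2: str) -> float:
        key = (go1, go2) if go1 <= go2 else (go2, go1)
        sim = self._pairs.get(key)
        if sim is None:
            if self.graph.is_root(go1) or self.graph.is_root(go2):
                raise OntologyError("root terms carry no information")
            s1, s2 = self.closure(go1), self.closure(go2)
            union = len(s1 | s2)
            sim = len(s1 & s2) / union if union else 0.0
            self._pairs[key] = sim
        return sim


# -- background term frequencies ------------------------------------------


@dataclass
class TermFrequencyTable:
    """Per-term background frequencies among GO-annotated proteins.

    ``counts[t]`` is the number of background proteins whose direct
    annotation lists ``t`` (once per protein), and ``n_proteins`` is the
    number of proteins with at least one GO term.
    """

    counts: Counter = field(default_factory=Counter)
    n_proteins: int = 0

    def frequency(self, term: str) -> float:
        return self.counts.get(term, 0) / self.n_proteins

    def abundant_terms(self, cutoff: float = 0.05) -> frozenset[str]:
        """Terms whose background frequency strictly exceeds ``cutoff``."""
        if not 0.0 <= cutoff <= 1.0:
            raise ValueError("cutoff must be in [0, 1]")
        thresh = cutoff * self.n_proteins
        return frozenset(t for t, c in self.counts.items() if c > thresh)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_proteins={self.n_proteins}\n")
            for term, count in sorted(self.counts.items()):
                fh.write(f"{term}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "TermFrequencyTable":
        counts: Counter = Counter()
        n_proteins = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    n_proteins = int(line.split("n_proteins=")[1])
                    continue
                term, count = line.split("\t")
                counts[term] = int(count)
        return cls(counts, n_proteins)


def term_frequencies(background) -> TermFrequencyTable:
    """Tally direct-annotation term frequencies over a background pool.

    ``background`` is any iterable of ``(protein_id, {namespace: term set})``
    pairs (an :class:`~pacscore.annotations.BackgroundPool` or the items of
    an :class:`~pacscore.annotations.AnnotationMap`).  Each term counts at
    most once per protein.
    """
    counts: Counter = Counter()
    n_proteins = 0
    for _pid, by_ns in background:
        terms = set().union(*by_ns.values()) if by_ns else set()
        if not terms:
            continue
        n_proteins += 1
        counts.update(terms)
    if n_proteins == 0:
        raise ValueError("background pool has no annotated protein")
    return TermFrequencyTable(counts, n_proteins)
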