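"""Genome gene tables, GO annotation maps, and the randomization null.

A :class:`GenomeTable` holds the gene order along each replicon (with
strand and optional operon assignments); an :class:`AnnotationMap` holds
per-gene GO term sets split by namespace.  The randomization null model
re-annotates each annotated gene with the complete term sets of a protein
drawn uniformly from a background pool, preserving *which* genes are
annotated while destroying *what* the annotation is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .ontology import NAMESPACES, OntologyGraph, TermFrequencyTable, UnknownTermError

logger = logging.getLogger(__name__)


@dataclass
class GeneRecord:
    """One gene: position in the gene order of a replicon, strand, operon."""

    gene_id: str
    replicon_id: str
    rank: int
    strand: str
    operon_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


class GenomeTable:
    """Ordered genes per replicon with topology (circular or linear)."""

    def __init__(
        self,
        records: Iterable[GeneRecord],
        topology: Mapping[str, str] | str = "circular",
    ) -> None:
        self._by_replicon: dict[str, list[GeneRecord]] = {}
        self._index: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._index:
                raise ValueError(f"duplicate gene_id {rec.gene_id}")
            self._index[rec.gene_id] = rec
            self._by_replicon.setdefault(rec.replicon_id, []).append(rec)
        for replicon, recs in self._by_replicon.items():
            recs.sort(key=lambda r: r.rank)
            if [r.rank for r in recs] != list(range(len(recs))):
                raise ValueError(f"ranks on {replicon} are not consecutive from 0")
        if isinstance(topology, str):
            self.topology = {rep: topology for rep in self._by_replicon}
        else:
            self.topology = {
                rep: topology.get(rep, "circular") for rep in self._by_replicon
            }
        for rep, topo in self.topology.items():
            if topo not in {"circular", "linear"}:
                raise ValueError(f"topology of {rep} must be circular or linear")
        self._check_operons()

    def _check_operons(self) -> None:
        # operon members should be contiguous in rank and on one strand;
        # real operon calls occasionally violate this, so warn only
        for recs in self._by_replicon.values():
            seen: dict[str, GeneRecord] = {}
            prev = None
            for rec in recs:
                op = rec.operon_id
                if op is None:
                    prev = None
                    continue
                if op in seen and (prev is None or prev.operon_id != op):
                    logger.warning("operon %s is not contiguous in rank", op)
                if op in seen and seen[op].strand != rec.strand:
                    logger.warning("operon %s spans both strands", op)
                seen.setdefault(op, rec)
                prev = rec

    # -- access ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._index[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for recs in self._by_replicon.values() for r in recs]

    @property
    def replicons(self) -> list[str]:
        return list(self._by_replicon)

    def replicon_genes(self, replicon_id: str) -> list[GeneRecord]:
        return list(self._by_replicon[replicon_id])

    # -- IO ----------------------------------------------------------------

    TSV_COLUMNS = ("replicon", "gene_id", "start", "end", "strand", "operon_id")

    @classmethod
    def from_tsv(cls, path: str, topology: Mapping[str, str] | str = "circular"):
        """Read a gene table TSV: replicon, gene_id, start, end, strand
        and an optional operon_id column; 1-based inclusive coordinates.
        Genes are ordered by start coordinate within each replicon."""
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for col in ("replicon", "gene_id", "start", "end", "strand"):
                if col not in idx:
                    raise ValueError(f"gene table missing column {col!r}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                operon = None
                if "operon_id" in idx and len(parts) > idx["operon_id"]:
                    operon = parts[idx["operon_id"]] or None
                rows.append(
                    (
                        parts[idx["replicon"]],
                        parts[idx["gene_id"]],
                        int(parts[idx["start"]]),
                        parts[idx["strand"]],
                        operon,
                    )
                )
        return cls(_rank_rows(rows), topology)

    @classmethod
    def from_gff3(
        cls,
        path: str,
        topology: Mapping[str, str] | str = "circular",
        feature_type: str = "gene",
        operons: Mapping[str, str] | None = None,
    ):
        """Read gene features from a GFF3 file (``ID`` attribute = gene_id)."""
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for feat in db.features_of_type(feature_type):
            gene_id = feat.attributes["ID"][0]
            if feat.strand not in {"+", "-"}:
                raise ValueError(f"gene {gene_id}: missing strand in GFF3")
            operon = operons.get(gene_id) if operons else None
            rows.append((feat.seqid, gene_id, feat.start, feat.strand, operon))
        return cls(_rank_rows(rows), topology)

    def to_tsv(self, path: str) -> None:
        """Write the table in the TSV dialect (synthetic 100 bp gene spacing)."""
        with open(path, "w") as fh:
            fh.write("\t".join(self.TSV_COLUMNS) + "\n")
            for rep in self.replicons:
                for rec in self._by_replicon[rep]:
                    start = rec.rank * 100 + 1
                    fh.write(
                        f"{rep}\t{rec.gene_id}\t{start}\t{start + 89}\t"
                        f"{rec.strand}\t{rec.operon_id or ''}\n"
                    )


def _rank_rows(rows) -> list[GeneRecord]:
    records = []
    by_rep: dict[str, list] = {}
    for row in rows:
        by_rep.setdefault(row[0], []).append(row)
    for rep, rep_rows in by_rep.items():
        rep_rows.sort(key=lambda r: r[2])
        for rank, (replicon, gene_id, _start, strand, operon) in enumerate(rep_rows):
            records.append(GeneRecord(gene_id, replicon, rank, strand, operon))
    return records


def read_operon_table(path: str) -> dict[str, str]:
    """Read a two-column TSV mapping gene_id -> operon_id."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[1]:
                mapping[parts[0]] = parts[1]
    return mapping


# -- annotation maps ------------------------------------------------------


def _empty_by_ns() -> dict[str, set[str]]:
    return {ns: set() for ns in NAMESPACES}


class AnnotationMap:
    """Per-gene, per-namespace GO term sets.

    Terms are primary (alt_id-resolved) identifiers; a namespace entry may
    be empty, meaning the gene is unannotated in that namespace.
    """

    def __init__(self, terms_of: Mapping[str, Mapping[str, set]] | None = None):
        self.terms_of: dict[str, dict[str, set[str]]] = {}
        for gene, by_ns in (terms_of or {}).items():
            entry = _empty_by_ns()
            for ns, terms in by_ns.items():
                entry[ns] = set(terms)
            self.terms_of[gene] = entry

    def __getitem__(self, gene_id: str) -> dict[str, set[str]]:
        return self.terms_of.get(gene_id, _empty_by_ns())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.terms_of

    def __iter__(self) -> Iterator[tuple[str, dict[str, set[str]]]]:
        return iter(self.terms_of.items())

    def __len__(self) -> int:
        return len(self.terms_of)

    def add(self, gene_id: str, namespace: str, term: str) -> None:
        self.terms_of.setdefault(gene_id, _empty_by_ns())[namespace].add(term)

    def terms(self, gene_id: str, namespace: str) -> set[str]:
        return self[gene_id][namespace]

    def annotated_genes(self) -> list[str]:
        """Genes carrying at least one GO term in any namespace."""
        return [
            g for g, by_ns in self.terms_of.items() if any(by_ns[ns] for ns in NAMESPACES)
        ]

    def copy(self) -> "AnnotationMap":
        return AnnotationMap(self.terms_of)

    def without_terms(self, removed: frozenset[str]) -> "AnnotationMap":
        """A new map with ``removed`` terms deleted from every direct set."""
        out = AnnotationMap()
        for gene, by_ns in self.terms_of.items():
            out.terms_of[gene] = {
                ns: set(terms) - removed for ns, terms in by_ns.items()
            }
        return out

    # -- IO ----------------------------------------------------------------

    @classmethod
    def read_gaf(
        cls,
        path: str,
        graph: OntologyGraph,
        aliases: Mapping[str, str] | None = None,
    ) -> "AnnotationMap":
        """Read a GAF 2.x association file.

        Rows with a ``NOT`` qualifier are skipped, alt_ids are resolved,
        terms absent from the ontology are dropped with a warning, and
        terms are bucketed by their ontology namespace (the GAF aspect
        column is ignored in favour of the ontology itself).  ``aliases``
        optionally remaps GAF object identifiers to gene-table gene_ids.
        """
        out = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("!") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    logger.warning("GAF line %d malformed; skipped", lineno)
                    continue
                _db, obj_id, _symbol, qualifier, term = parts[:5]
                if "NOT" in qualifier.split("|"):
                    continue
                gene_id = (aliases or {}).get(obj_id, obj_id)
                try:
                    term = graph.resolve(term)
                except UnknownTermError:
                    logger.warning(
                        "GAF line %d: term %s not in ontology; dropped", lineno, term
                    )
                    continue
                if graph.is_root(term):
                    continue
                out.add(gene_id, graph.namespace_of[term], term)
        return out

    @classmethod
    def read_mapping(cls, path: str, graph: OntologyGraph) -> "AnnotationMap":
        """Read a simple two-column TSV of (gene_id, GO term)."""
        out = cls()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or line.startswith("#"):
                    continue
                gene_id, term = parts[0], parts[1]
                try:
                    term = graph.resolve(term)
                except UnknownTermError:
                    logger.warning("term %s not in ontology; dropped", term)
                    continue
                if graph.is_root(term):
                    continue
                out.add(gene_id, graph.namespace_of[term], term)
        return out

    _ASPECT = {"BP": "P", "MF": "F", "CC": "C"}

    def to_gaf(self, path: str, db: str = "pacscore") -> None:
        """Write a minimal GAF 2.2 file (one row per gene-term pair)."""
        with open(path, "w") as fh:
            fh.write("!gaf-version: 2.2\n")
            for gene in sorted(self.terms_of):
                for ns in NAMESPACES:
                    for term in sorted(self.terms_of[gene][ns]):
                        fh.write(
                            f"{db}\t{gene}\t{gene}\tenables\t{term}\tREF\tIEA\t\t"
                            f"{self._ASPECT[ns]}\t\t\tprotein\ttaxon:0\t20260101\t{db}\t\t\n"
                        )

    def filter_abundant(
        self, freqs: TermFrequencyTable, cutoff: float = 0.05
    ) -> tuple["AnnotationMap", frozenset[str]]:
        """Drop terms whose background frequency exceeds ``cutoff``.

        Returns the filtered map and the removed term set; the caller
        should also pass the removed set to the similarity scorer so the
        terms are excluded from ancestor closures.
        """
        removed = freqs.abundant_terms(cutoff)
        return self.without_terms(removed), removed


def filter_abundant_terms(
    annotations: AnnotationMap, freqs: TermFrequencyTable, cutoff: float = 0.05
) -> tuple[AnnotationMap, frozenset[str]]:
    """Functional alias for :meth:`AnnotationMap.filter_abundant`."""
    return annotations.filter_abundant(freqs, cutoff)


# -- background pool and the randomization null ---------------------------


@dataclass
class BackgroundPool:
    """A pool of GO-annotated proteins used for random-annotation draws.

    Entries are ``(protein_id, {namespace: term set})`` pairs; proteins
    without any GO term are excluded at construction.
    """

    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [
            (pid, by_ns)
            for pid, by_ns in self.entries
            if any(by_ns.get(ns) for ns in NAMESPACES)
        ]
        if not self.entries:
            raise ValueError("background pool is empty")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_annotation_map(cls, annotations: AnnotationMap) -> "BackgroundPool":
        return cls([(g, by_ns) for g, by_ns in annotations])


def random_annotation(
    annotations: AnnotationMap, pool: BackgroundPool, seed: int
) -> AnnotationMap:
    """The randomization null: re-annotate each annotated gene at random.

    Every gene carrying at least one GO term receives the complete
    per-namespace term sets of one protein drawn uniformly (with
    replacement across genes) from the pool; unannotated genes stay
    unannotated.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = AnnotationMap()
    genes = sorted(annotations.annotated_genes())
    draws = rng.integers(0, len(pool), size=len(genes))
    for gene, k in zip(genes, draws):
        _pid, by_ns = pool.entries[int(k)]
        out.terms_of[gene] = {ns: set(by_ns.get(ns, ())) for ns in NAMESPACES}
    return out
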