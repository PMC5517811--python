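"""Gene-neighborhood observation profiles.

For each gene G, the six chromosomal neighbors at offsets -3..-1, +1..+3
(never crossing a replicon boundary; circular replicons wrap) contribute
one observation per GO namespace: the gene function similarity (GFS)
between G and the neighbor, defined as the maximum term-pair similarity
over all cross pairs of their term sets.  An observation is MISSING
(``gfs is None``) when either gene has no annotation in that namespace.

Modes
-----
``plain``   GFS only.
``strand``  GFS plus a same-strand flag (likelihoods conditioned on it).
``operon``  GFS kept only for neighbors sharing the gene's operon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .annotations import AnnotationMap, GenomeTable
from .ontology import NAMESPACES, SimilarityScorer

MODES = ("plain", "operon", "strand", "dependent")
OFFSETS = (-3, -2, -1, 1, 2, 3)


@dataclass
class Observation:
    """One (offset, namespace) cell of a gene's profile."""

    offset: int
    namespace: str
    gfs: float | None
    same_strand: bool | None = None
    same_operon: bool | None = None


@dataclass
class ObservationProfile:
    gene_id: str
    observations: list[Observation]

    @property
    def eligible(self) -> bool:
        """True if at least one GFS observation is available."""
        return any(o.gfs is not None for o in self.observations)

    @property
    def n_obs(self) -> int:
        return sum(1 for o in self.observations if o.gfs is not None)


def neighbors(
    genome: GenomeTable, gene_id: str, window: int = 3
) -> dict[int, str]:
    """Map offset -> neighbor gene_id within ``window`` genes of ``gene_id``.

    Circular replicons wrap around; linear replicons truncate at the ends
    (absent offsets are simply missing from the mapping).  On a replicon
    shorter than ``2*window + 1`` a wrap that would reach the gene itself
    (or revisit a neighbor) yields no entry for that offset.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rec = genome[gene_id]
    replicon = genome.replicon_genes(rec.replicon_id)
    n = len(replicon)
    circular = genome.topology[rec.replicon_id] == "circular"
    out: dict[int, str] = {}
    seen = {rec.rank}
    for magnitude in range(1, window + 1):
        for offset in (-magnitude, magnitude):
            idx = rec.rank + offset
            if circular:
                idx %= n
            elif not 0 <= idx < n:
                continue
            if idx in seen:  # tiny replicon: window self-overlap
                continue
            seen.add(idx)
            out[offset] = replicon[idx].gene_id
    return out


def gene_function_similarity(
    scorer: SimilarityScorer,
    a1: Iterable[str],
    a2: Iterable[str],
) -> float | None:
    """Max term-pair similarity over all cross pairs; None if a set is empty."""
    a1, a2 = list(a1), list(a2)
    if not a1 or not a2:
        return None
    sim = scorer.similarity
    best = 0.0
    for t1 in a1:
        for t2 in a2:
            s = sim(t1, t2)
            if s > best:
                best = s
                if best == 1.0:
                    return 1.0
    return best


def build_profile(
    genome: GenomeTable,
    annotations: AnnotationMap,
    scorer: SimilarityScorer,
    gene_id: str,
    mode: str = "plain",
    window: int = 3,
) -> ObservationProfile:
    """Build the observation profile of one gene.

    In operon mode the GFS of a neighbor outside the gene's operon is set
    to MISSING (only same-operon neighbors count); a gene without an
    operon assignment, or whose operon is a singleton within the window,
    is ineligible.  In strand mode each observation carries a same-strand
    flag.  The ``dependent`` scoring variant uses plain profiles.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    rec = genome[gene_id]
    own = annotations[gene_id]
    nbrs = neighbors(genome, gene_id, window)
    obs: list[Observation] = []
    for offset in sorted(nbrs, key=lambda o: (abs(o), o)):
        nbr = genome[nbrs[offset]]
        nbr_terms = annotations[nbr.gene_id]
        same_strand = nbr.strand == rec.strand
        same_operon = (
            rec.operon_id is not None and nbr.operon_id == rec.operon_id
        )
        for ns in NAMESPACES:
            gfs = gene_function_similarity(scorer, own[ns], nbr_terms[ns])
            if mode == "operon" and not same_operon:
                gfs = None
            obs.append(
                Observation(
                    offset=offset,
                    namespace=ns,
                    gfs=gfs,
                    same_strand=same_strand if mode == "strand" else None,
                    same_operon=same_operon if mode == "operon" else None,
                )
            )
    return ObservationProfile(gene_id, obs)


def build_profiles(
    genome: GenomeTable,
    annotations: AnnotationMap,
    scorer: SimilarityScorer,
    mode: str = "plain",
    window: int = 3,
) -> list[ObservationProfile]:
    """Profiles for every gene of the genome, in gene order."""
    return [
        build_profile(genome, annotations, scorer, g, mode, window)
        for g in genome.gene_ids
    ]


def profiles_to_tsv(profiles: Iterable[ObservationProfile], path: str) -> None:
    """Long-format export: gene_id, offset, namespace, gfs, flags."""
    with open(path, "w") as fh:
        fh.write("gene_id\toffset\tnamespace\tgfs\tsame_strand\tsame_operon\n")
        for prof in profiles:
            for o in prof.observations:
                gfs = "" if o.gfs is None else f"{o.gfs:.6g}"
                ss = "" if o.same_strand is None else int(o.same_strand)
                so = "" if o.same_operon is None else int(o.same_operon)
                fh.write(
                    f"{prof.gene_id}\t{o.offset}\t{o.namespace}\t{gfs}\t{ss}\t{so}\n"
                )
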