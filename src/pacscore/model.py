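"""Model/Results interface tying the pipeline together.

:class:`AnnotationConfidenceModel` is constructed from a genome, its GO
annotations and an ontology; :meth:`~AnnotationConfidenceModel.fit`
filters abundant terms, builds neighborhood profiles under the given
annotation and under a seeded randomized annotation, estimates the
likelihood tables, scores every gene, and returns an
:class:`AnnotationConfidenceResults` carrying the per-gene PACs, the
genome AQS, the fitted likelihood model and diagnostics
(calibration curve, shuffle experiment, random-annotation baseline).
"""

from __future__ import annotations

import logging

import pandas as pd

from .annotations import (
    AnnotationMap,
    BackgroundPool,
    GenomeTable,
    random_annotation,
)
from .experiments import ShuffleDesign, ShuffleSummary, run_shuffle_experiment
from .likelihood import (
    BinningScheme,
    ChainLikelihoodModel,
    LikelihoodModel,
    estimate,
    estimate_chain,
)
from .neighborhood import MODES, build_profiles
from .ontology import OntologyGraph, SimilarityScorer, term_frequencies
from .pac import GenomeScore, calibration_curve, score_profiles

logger = logging.getLogger(__name__)


class AnnotationConfidenceModel:
    """Bayesian annotation-confidence model for one genome.

    Parameters
    ----------
    genome
        Gene order, strands and (for operon mode) operon assignments.
    annotations
        The annotation under assessment (assumed correct for estimation).
    ontology
        The GO is-a DAG.
    background
        Pool for term-frequency filtering and random-annotation draws;
        defaults to the genome's own annotations (logged), which keeps a
        study self-contained at the cost of a genome-specific null.
    mode
        ``plain`` (independent), ``operon``, ``strand`` or ``dependent``.
    """

    def __init__(
        self,
        genome: GenomeTable,
        annotations: AnnotationMap,
        ontology: OntologyGraph,
        background: BackgroundPool | None = None,
        mode: str = "plain",
        window: int = 3,
        term_frequency_cutoff: float = 0.05,
        n_bins: int = 10,
        pseudocount: float = 1.0,
        prior_correct: float = 0.5,
    ) -> None:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.genome = genome
        self.annotations = annotations
        self.ontology = ontology
        if background is None:
            logger.info(
                "no background pool supplied; using the genome's own "
                "annotations as the random-annotation pool"
            )
            background = BackgroundPool.from_annotation_map(annotations)
        self.background = background
        self.mode = mode
        self.window = window
        self.term_frequency_cutoff = term_frequency_cutoff
        self.scheme = BinningScheme(n_bins)
        self.pseudocount = pseudocount
        self.prior_correct = prior_correct

    @property
    def profile_mode(self) -> str:
        return "plain" if self.mode == "dependent" else self.mode

    def prepare(self) -> tuple[AnnotationMap, SimilarityScorer]:
        """Abundant-term filtering shared by fit() and transfer scoring."""
        freqs = term_frequencies(self.background)
        filtered, removed = self.annotations.filter_abundant(
            freqs, self.term_frequency_cutoff
        )
        logger.info(
            "filtered %d abundant terms (> %.1f%% of %d background proteins)",
            len(removed),
            100 * self.term_frequency_cutoff,
            freqs.n_proteins,
        )
        scorer = SimilarityScorer(self.ontology, removed)
        return filtered, scorer

    def _filtered_pool(self, removed: frozenset[str]) -> BackgroundPool:
        entries = []
        for pid, by_ns in self.background:
            trimmed = {ns: set(terms) - removed for ns, terms in by_ns.items()}
            if any(trimmed.values()):
                entries.append((pid, trimmed))
        return BackgroundPool(entries)

    def fit(
        self, seed: int = 0, likelihoods: LikelihoodModel | ChainLikelihoodModel | None = None
    ) -> "AnnotationConfidenceResults":
        """Estimate likelihoods (unless transferred in) and score the genome.

        ``seed`` drives the randomized annotation that defines the
        incorrect-annotation hypothesis.  Pass ``likelihoods`` to score
        with tables transferred from another genome instead of
        re-estimating them.
        """
        filtered, scorer = self.prepare()
        pool = self._filtered_pool(scorer.excluded)
        randomized = random_annotation(filtered, pool, seed)
        profiles = build_profiles(
            self.genome, filtered, scorer, self.profile_mode, self.window
        )
        random_profiles = build_profiles(
            self.genome, randomized, scorer, self.profile_mode, self.window
        )
        if likelihoods is None:
            if self.mode == "dependent":
                likelihoods = estimate_chain(
                    profiles, random_profiles, self.scheme, self.pseudocount
                )
            else:
                likelihoods = estimate(
                    profiles,
                    random_profiles,
                    self.scheme,
                    self.pseudocount,
                    self.mode,
                )
        else:
            base = (
                likelihoods.marginal
                if isinstance(likelihoods, ChainLikelihoodModel)
                else likelihoods
            )
            if not base.compatible_with(self.profile_mode):
                raise ValueError(
                    f"transferred model (mode {base.mode!r}) cannot score "
                    f"{self.mode!r} profiles"
                )
        scores = score_profiles(profiles, likelihoods, self.prior_correct)
        random_scores = score_profiles(
            random_profiles, likelihoods, self.prior_correct
        )
        return AnnotationConfidenceResults(
            self, likelihoods, scorer, filtered, randomized, scores,
            random_scores, seed,
        )


class AnnotationConfidenceResults:
    """Fitted results: per-gene PACs, AQS, likelihoods and diagnostics."""

    def __init__(
        self,
        model: AnnotationConfidenceModel,
        likelihoods: LikelihoodModel | ChainLikelihoodModel,
        scorer: SimilarityScorer,
        filtered_annotations: AnnotationMap,
        randomized_annotations: AnnotationMap,
        scores: GenomeScore,
        random_scores: GenomeScore,
        seed: int,
    ) -> None:
        self.model = model
        self.likelihoods = likelihoods
        self.scorer = scorer
        self.filtered_annotations = filtered_annotations
        self.randomized_annotations = randomized_annotations
        self.scores = scores
        self.random_scores = random_scores
        self.seed = seed

    # -- headline quantities ---------------------------------------------

    @property
    def aqs(self) -> float:
        """Fraction of eligible genes with PAC in [0.95, 1]."""
        return self.scores.aqs

    @property
    def aqs_random(self) -> float:
        """Same fraction under the randomized annotation (null baseline)."""
        return self.random_scores.aqs

    @property
    def n_eligible(self) -> int:
        return self.scores.n_eligible

    @property
    def pac(self) -> pd.DataFrame:
        """Per-gene table: gene_id, n_obs, pac (NaN for ineligible genes)."""
        return self.scores.to_dataframe()

    def calibration(self) -> pd.DataFrame:
        """Reliability curve pooling correct- and random-annotation PACs."""
        return calibration_curve(self.scores, self.random_scores)

    def score_annotations(self, annotations: AnnotationMap) -> GenomeScore:
        """Score an alternative annotation of the same genome.

        The alternative annotation is filtered with the same abundant-term
        set and scored with the fitted likelihood tables (which are not
        re-estimated), so AQS values are directly comparable.
        """
        filtered = annotations.without_terms(self.scorer.excluded)
        profiles = build_profiles(
            self.model.genome,
            filtered,
            self.scorer,
            self.model.profile_mode,
            self.model.window,
        )
        return score_profiles(profiles, self.likelihoods, self.model.prior_correct)

    def shuffle_experiment(
        self, nr_grid, repeats: int = 100, seed: int = 0
    ) -> ShuffleSummary:
        """Pair-swap sensitivity experiment with the fitted model held fixed."""
        return run_shuffle_experiment(
            self.model.genome,
            self.filtered_annotations,
            self.scorer,
            self.likelihoods,
            nr_grid,
            ShuffleDesign(repeats=repeats, seed=seed),
            self.model.profile_mode,
            self.model.prior_correct,
            self.model.window,
        )

    def save_model(self, path: str) -> None:
        """Persist the likelihood tables for cross-genome transfer."""
        if isinstance(self.likelihoods, ChainLikelihoodModel):
            raise NotImplementedError(
                "chain models are not serialized; transfer the independent model"
            )
        self.likelihoods.save(path)

    def summary(self) -> str:
        m = self.model
        lines = [
            "        Annotation Confidence Model Results",
            "=" * 52,
            f"Mode:            {m.mode:<10}  Genes:          {self.scores.n_genes}",
            f"Prior P(A_c):    {m.prior_correct:<10.3g}  Eligible:       {self.n_eligible}",
            f"Bins:            {m.scheme.n_bins:<10d}  PAC>=0.95:      {self.scores.top_bin_count}",
            f"Pseudocount:     {m.pseudocount:<10.3g}  AQS:            {self.aqs:.3f}",
            f"Cutoff:          {m.term_frequency_cutoff:<10.3g}  AQS (random):   {self.aqs_random:.3f}",
            f"Filtered terms:  {len(self.scorer.excluded):<10d}  Seed:           {self.seed}",
            "=" * 52,
        ]
        return "\n".join(lines)
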