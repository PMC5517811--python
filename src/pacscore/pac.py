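"""Per-gene annotation-confidence posteriors and genome-level summaries.

PAC (probability of annotation confidence) is the Bayes posterior that a
gene's annotation is correct given its neighborhood observation profile,
assuming the observations are conditionally independent:

    Pr(A_c | O) = prior * prod_i Pr(O_i|A_c)
                  / (prior * prod_i Pr(O_i|A_c)
                     + (1-prior) * prod_i Pr(O_i|A_inc))

MISSING observations are skipped from both products (absent information
is assumed equally likely under either hypothesis).  A gene with no
available observation is ineligible and gets no PAC.  The genome-level
AQS (annotation quality score) is the fraction of eligible genes whose
PAC falls in the top histogram bin [0.95, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotations import AnnotationMap, GenomeTable
from .likelihood import ChainLikelihoodModel, LikelihoodModel, _toward_gene
from .neighborhood import ObservationProfile, build_profiles
from .ontology import SimilarityScorer

#: PAC histogram: 20 bins of width 0.05, [0, 0.05), ..., [0.95, 1] closed
N_HIST_BINS = 20
TOP_BIN_LEFT = 0.95


def hist_bin(pac: float) -> int:
    x = pac * N_HIST_BINS
    i = int(x)
    if x - i > 1 - 1e-9:  # 0.95 * 20 is 18.999... in binary floating point
        i += 1
    return min(i, N_HIST_BINS - 1)


@dataclass
class PacResult:
    gene_id: str
    pac: float | None  # None = ineligible
    n_obs: int


def _check_prior(prior: float) -> None:
    if not 0.0 < prior < 1.0:
        raise ValueError("prior_correct must lie strictly inside (0, 1)")


def pac_for_gene(
    profile: ObservationProfile,
    model: LikelihoodModel,
    prior_correct: float = 0.5,
) -> PacResult:
    """Independent-model posterior for one gene (log-space products)."""
    _check_prior(prior_correct)
    log_c = math.log(prior_correct)
    log_i = math.log(1.0 - prior_correct)
    n_obs = 0
    for obs in profile.observations:
        if obs.gfs is None:
            continue
        n_obs += 1
        log_c += math.log(model.lookup(obs, "correct"))
        log_i += math.log(model.lookup(obs, "incorrect"))
    if n_obs == 0:
        return PacResult(profile.gene_id, None, 0)
    m = max(log_c, log_i)
    pac = math.exp(log_c - m) / (math.exp(log_c - m) + math.exp(log_i - m))
    return PacResult(profile.gene_id, pac, n_obs)


def pac_dependent(
    profile: ObservationProfile,
    chain_model: ChainLikelihoodModel,
    prior_correct: float = 0.5,
) -> PacResult:
    """Chain-model posterior: O_±2 conditions on O_±1, O_±3 on O_±2.

    When the conditioning observation is MISSING, the conditioned
    observation falls back to its marginal table; with conditionals equal
    to marginals this reduces exactly to :func:`pac_for_gene`.
    """
    _check_prior(prior_correct)
    by_cell = {
        (o.offset, o.namespace): o for o in profile.observations if o.gfs is not None
    }
    if not by_cell:
        return PacResult(profile.gene_id, None, 0)
    log_c = math.log(prior_correct)
    log_i = math.log(1.0 - prior_correct)
    for (offset, ns), obs in by_cell.items():
        toward = _toward_gene(offset)
        cond = by_cell.get((toward, ns)) if toward is not None else None
        log_c += math.log(chain_model.lookup(obs, cond, "correct"))
        log_i += math.log(chain_model.lookup(obs, cond, "incorrect"))
    m = max(log_c, log_i)
    pac = math.exp(log_c - m) / (math.exp(log_c - m) + math.exp(log_i - m))
    return PacResult(profile.gene_id, pac, len(by_cell))


@dataclass
class GenomeScore:
    """Per-gene PACs plus the genome summary (AQS, PAC histogram)."""

    results: list[PacResult]
    n_genes: int = 0
    n_eligible: int = 0
    aqs: float = float("nan")
    bin_counts: np.ndarray = field(default_factory=lambda: np.zeros(N_HIST_BINS, int))

    def __post_init__(self) -> None:
        self.n_genes = len(self.results)
        eligible = [r for r in self.results if r.pac is not None]
        self.n_eligible = len(eligible)
        self.bin_counts = np.zeros(N_HIST_BINS, dtype=int)
        for r in eligible:
            self.bin_counts[hist_bin(r.pac)] += 1
        self.aqs = (
            self.bin_counts[-1] / self.n_eligible if self.n_eligible else float("nan")
        )

    @property
    def top_bin_count(self) -> int:
        return int(self.bin_counts[-1])

    def pacs(self) -> np.ndarray:
        return np.array([r.pac for r in self.results if r.pac is not None])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.results],
                "n_obs": [r.n_obs for r in self.results],
                "pac": [r.pac for r in self.results],
            }
        )

    def to_tsv(self, path: str) -> None:
        df = self.to_dataframe()
        df["pac"] = df["pac"].map(lambda p: "" if pd.isna(p) else f"{p:.6g}")
        df.to_csv(path, sep="\t", index=False)

    def summary_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_eligible": self.n_eligible,
            "aqs": self.aqs,
            "bin_counts": self.bin_counts.tolist(),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1)


def score_profiles(
    profiles: Iterable[ObservationProfile],
    model: LikelihoodModel | ChainLikelihoodModel,
    prior_correct: float = 0.5,
) -> GenomeScore:
    """PAC for each profile; chain models use the dependent factorization."""
    if isinstance(model, ChainLikelihoodModel):
        results = [pac_dependent(p, model, prior_correct) for p in profiles]
    else:
        results = [pac_for_gene(p, model, prior_correct) for p in profiles]
    return GenomeScore(results)


def score_genome(
    genome: GenomeTable,
    annotations: AnnotationMap,
    scorer: SimilarityScorer,
    model: LikelihoodModel | ChainLikelihoodModel,
    mode: str = "plain",
    prior_correct: float = 0.5,
    window: int = 3,
) -> GenomeScore:
    """Build profiles for every gene and score them under the model."""
    base = model.marginal if isinstance(model, ChainLikelihoodModel) else model
    if not base.compatible_with(mode):
        raise ValueError(
            f"model estimated in mode {base.mode!r} cannot score {mode!r} profiles"
        )
    profile_mode = "plain" if mode == "dependent" else mode
    profiles = build_profiles(genome, annotations, scorer, profile_mode, window)
    return score_profiles(profiles, model, prior_correct)


def calibration_curve(
    scores_correct: GenomeScore, scores_random: GenomeScore
) -> pd.DataFrame:
    """Reliability table over pooled correct- and random-annotation PACs.

    Each eligible gene contributes its correct-annotation PAC (labelled
    correct) and its random-annotation PAC (labelled incorrect) to shared
    bins; per bin the fraction of correct annotations is reported against
    the bin's right end.  Bins with no members get fraction NaN (empty,
    not zero).
    """
    n_corr = np.zeros(N_HIST_BINS, dtype=int)
    n_inc = np.zeros(N_HIST_BINS, dtype=int)
    for r in scores_correct.results:
        if r.pac is not None:
            n_corr[hist_bin(r.pac)] += 1
    for r in scores_random.results:
        if r.pac is not None:
            n_inc[hist_bin(r.pac)] += 1
    total = n_corr + n_inc
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, n_corr / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_right_end": np.arange(1, N_HIST_BINS + 1) * 0.05,
            "n_correct": n_corr,
            "n_incorrect": n_inc,
            "fraction_correct": frac,
        }
    )
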