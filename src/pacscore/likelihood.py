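"""Empirical likelihood tables for the Bayes classifier.

The continuous GFS observations are discretized into equal-width bins over
[0, 1] (left-closed, last bin closed) and per-cell conditional
probabilities are estimated as Laplace-smoothed empirical frequencies:

    Pr(bin | cell) = (count + alpha) / (N + alpha * K)

with one cell per (offset, namespace) — doubled into same/opposite-strand
sub-tables in strand mode — and one table set under the correct-annotation
hypothesis (the genome's given annotation) and one under the
incorrect-annotation hypothesis (a randomized annotation).  MISSING
observations contribute nothing to estimation.

The dependent-model variant additionally estimates first-order chain
conditionals Pr(bin_i | bin_toward_G, hypothesis) for adjacent offset
pairs in each direction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .neighborhood import Observation, ObservationProfile

FORMAT_VERSION = 1

HYPOTHESES = ("correct", "incorrect")


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width bins over [0, 1]; bin_of(0) = 0, bin_of(1) = n_bins - 1."""

    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    def bin_of(self, value: float) -> int:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"GFS value {value} outside [0, 1]")
        x = value * self.n_bins
        i = int(x)
        if x - i > 1 - 1e-9:  # counteract representation error at bin edges
            i += 1
        return min(i, self.n_bins - 1)


def _cell_key(obs: Observation, mode: str) -> tuple:
    if mode == "strand":
        if obs.same_strand is None:
            raise ValueError("strand-mode observation lacks a strand flag")
        return (obs.offset, obs.namespace, bool(obs.same_strand))
    return (obs.offset, obs.namespace)


class LikelihoodModel:
    """Per-cell binned conditional probabilities under both hypotheses.

    ``tables[hyp][key]`` is a probability vector over bins and
    ``counts[hyp][key]`` the raw bin counts, with ``key = (offset,
    namespace)`` or ``(offset, namespace, same_strand)`` in strand mode.
    """

    def __init__(
        self,
        scheme: BinningScheme,
        pseudocount: float,
        mode: str,
        tables: dict[str, dict[tuple, np.ndarray]],
        counts: dict[str, dict[tuple, np.ndarray]],
        source: str = "",
    ) -> None:
        self.scheme = scheme
        self.pseudocount = pseudocount
        self.mode = mode
        self.tables = tables
        self.counts = counts
        self.source = source

    def lookup(self, obs: Observation, hypothesis: str) -> float:
        """Bin probability of a non-MISSING observation under a hypothesis."""
        if obs.gfs is None:
            raise ValueError("MISSING observation; callers must skip it")
        key = _cell_key(obs, self.mode)
        vec = self.tables[hypothesis].get(key)
        if vec is None:
            raise KeyError(f"no likelihood cell for {key}")
        return float(vec[self.scheme.bin_of(obs.gfs)])

    def log_likelihood_ratio(self, obs: Observation) -> float:
        return math.log(self.lookup(obs, "correct")) - math.log(
            self.lookup(obs, "incorrect")
        )

    def compatible_with(self, profile_mode: str) -> bool:
        """Profiles built in ``profile_mode`` can be scored by this model."""
        if self.mode == "strand":
            return profile_mode == "strand"
        if profile_mode == "strand":
            return False
        # plain, operon and dependent profiles share the (offset, ns) keying
        return True

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        def pack(hyp):
            return {
                "|".join(str(k) for k in key): {
                    "p": vec.tolist(),
                    "n": self.counts[hyp][key].tolist(),
                }
                for key, vec in self.tables[hyp].items()
            }

        return {
            "format_version": FORMAT_VERSION,
            "kind": "likelihood_model",
            "mode": self.mode,
            "n_bins": self.scheme.n_bins,
            "pseudocount": self.pseudocount,
            "source": self.source,
            "tables": {hyp: pack(hyp) for hyp in HYPOTHESES},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LikelihoodModel":
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported model file version {doc.get('format_version')!r}"
            )
        scheme = BinningScheme(doc["n_bins"])
        tables: dict[str, dict] = {h: {} for h in HYPOTHESES}
        counts: dict[str, dict] = {h: {} for h in HYPOTHESES}
        for hyp in HYPOTHESES:
            for skey, cell in doc["tables"][hyp].items():
                parts = skey.split("|")
                key: tuple
                if len(parts) == 3:
                    key = (int(parts[0]), parts[1], parts[2] == "True")
                else:
                    key = (int(parts[0]), parts[1])
                tables[hyp][key] = np.asarray(cell["p"], dtype=float)
                counts[hyp][key] = np.asarray(cell["n"], dtype=float)
        return cls(
            scheme,
            doc["pseudocount"],
            doc["mode"],
            tables,
            counts,
            doc.get("source", ""),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "LikelihoodModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _smooth(counts: np.ndarray, alpha: float) -> np.ndarray:
    n = counts.sum()
    k = len(counts)
    if n == 0 and alpha == 0:
        raise ValueError(
            "empty likelihood cell with pseudocount 0; use pseudocount > 0"
        )
    return (counts + alpha) / (n + alpha * k)


def _collect_keys(profiles: Iterable[ObservationProfile], mode: str) -> set[tuple]:
    keys = set()
    for prof in profiles:
        for obs in prof.observations:
            keys.add(_cell_key(obs, mode))
    return keys


def estimate(
    profiles_correct: list[ObservationProfile],
    profiles_random: list[ObservationProfile],
    scheme: BinningScheme = BinningScheme(),
    pseudocount: float = 1.0,
    mode: str = "plain",
    source: str = "",
) -> LikelihoodModel:
    """Estimate likelihood tables from correct and randomized profiles.

    Both collections must be built in the same mode over the same genome
    geometry.  Each cell's probability vector is the Laplace-smoothed bin
    frequency of its non-MISSING observations; estimation is invariant to
    profile order.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    keys = _collect_keys(profiles_correct, mode) | _collect_keys(
        profiles_random, mode
    )
    tables: dict[str, dict] = {h: {} for h in HYPOTHESES}
    counts: dict[str, dict] = {h: {} for h in HYPOTHESES}
    for hyp, profiles in (
        ("correct", profiles_correct),
        ("incorrect", profiles_random),
    ):
        raw = {key: np.zeros(scheme.n_bins) for key in keys}
        for prof in profiles:
            for obs in prof.observations:
                if obs.gfs is None:
                    continue
                raw[_cell_key(obs, mode)][scheme.bin_of(obs.gfs)] += 1
        for key, vec in raw.items():
            counts[hyp][key] = vec
            tables[hyp][key] = _smooth(vec, pseudocount)
    return LikelihoodModel(scheme, pseudocount, mode, tables, counts, source)


# -- dependent (chain) model ----------------------------------------------


def _toward_gene(offset: int) -> int | None:
    """The adjacent offset one step closer to the focal gene, if any."""
    if abs(offset) == 1:
        return None
    return offset - (1 if offset > 0 else -1)


class ChainLikelihoodModel:
    """First-order chain factorization of the neighborhood likelihood.

    Per direction the likelihood factorizes as
    Pr(O_±1|A) · Pr(O_±2|O_±1, A) · Pr(O_±3|O_±2, A); the marginal tables
    come from an embedded :class:`LikelihoodModel` and ``conditionals``
    maps (offset, namespace) for |offset| in {2, 3} to a K×K row-stochastic
    matrix (rows indexed by the toward-gene neighbor's bin).  When the
    conditioning observation is MISSING the marginal of the conditioned
    observation is used instead.
    """

    def __init__(
        self,
        marginal: LikelihoodModel,
        conditionals: dict[str, dict[tuple, np.ndarray]],
    ) -> None:
        if marginal.mode == "strand":
            raise ValueError("chain model supports plain/operon profiles only")
        self.marginal = marginal
        self.conditionals = conditionals

    @property
    def scheme(self) -> BinningScheme:
        return self.marginal.scheme

    def lookup(
        self, obs: Observation, conditioner: Observation | None, hypothesis: str
    ) -> float:
        """Pr(obs | conditioner, hypothesis); marginal if no conditioner."""
        if conditioner is None or conditioner.gfs is None or _toward_gene(
            obs.offset
        ) is None:
            return self.marginal.lookup(obs, hypothesis)
        key = (obs.offset, obs.namespace)
        mat = self.conditionals[hypothesis].get(key)
        if mat is None:
            return self.marginal.lookup(obs, hypothesis)
        row = self.scheme.bin_of(conditioner.gfs)
        col = self.scheme.bin_of(obs.gfs)
        return float(mat[row, col])


def estimate_chain(
    profiles_correct: list[ObservationProfile],
    profiles_random: list[ObservationProfile],
    scheme: BinningScheme = BinningScheme(),
    pseudocount: float = 1.0,
    source: str = "",
) -> ChainLikelihoodModel:
    """Estimate marginal plus adjacent-offset conditional tables."""
    marginal = estimate(
        profiles_correct, profiles_random, scheme, pseudocount, "plain", source
    )
    conditionals: dict[str, dict[tuple, np.ndarray]] = {h: {} for h in HYPOTHESES}
    for hyp, profiles in (
        ("correct", profiles_correct),
        ("incorrect", profiles_random),
    ):
        joint: dict[tuple, np.ndarray] = {}
        for prof in profiles:
            by_cell = {
                (o.offset, o.namespace): o
                for o in prof.observations
                if o.gfs is not None
            }
            for (offset, ns), obs in by_cell.items():
                toward = _toward_gene(offset)
                if toward is None:
                    continue
                cond = by_cell.get((toward, ns))
                if cond is None:
                    continue
                mat = joint.setdefault(
                    (offset, ns), np.zeros((scheme.n_bins, scheme.n_bins))
                )
                mat[scheme.bin_of(cond.gfs), scheme.bin_of(obs.gfs)] += 1
        for key, mat in joint.items():
            rows = np.stack([_smooth(row, pseudocount) for row in mat])
            conditionals[hyp][key] = rows
    return ChainLikelihoodModel(marginal, conditionals)
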