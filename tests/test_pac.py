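"""Bayes posterior (PAC), genome summaries (AQS) and calibration."""

import math

import numpy as np
import pytest

from pacscore import (
    BinningScheme,
    ChainLikelihoodModel,
    GenomeScore,
    LikelihoodModel,
    Observation,
    ObservationProfile,
    PacResult,
    calibration_curve,
    pac_dependent,
    pac_for_gene,
)


def toy_model(cells, n_bins=2, mode="plain"):
    """LikelihoodModel from {key: (correct vector, incorrect vector)}."""
    tables = {"correct": {}, "incorrect": {}}
    counts = {"correct": {}, "incorrect": {}}
    for key, (pc, pi) in cells.items():
        tables["correct"][key] = np.asarray(pc, float)
        tables["incorrect"][key] = np.asarray(pi, float)
        counts["correct"][key] = np.zeros(n_bins)
        counts["incorrect"][key] = np.zeros(n_bins)
    return LikelihoodModel(BinningScheme(n_bins), 1.0, mode, tables, counts)


class TestPacForGene:
    def test_profile_without_observations_is_ineligible(self):
        prof = ObservationProfile("g", [Observation(1, "BP", None)])
        model = toy_model({(1, "BP"): ([0.5, 0.5], [0.5, 0.5])})
        res = pac_for_gene(prof, model)
        assert res.pac is None
        assert res.n_obs == 0

    def test_likelihood_ratio_one_returns_the_prior(self):
        model = toy_model({(1, "BP"): ([0.3, 0.7], [0.3, 0.7])})
        prof = ObservationProfile("g", [Observation(1, "BP", 1.0)])
        assert pac_for_gene(prof, model).pac == 0.5
        assert pac_for_gene(prof, model, prior_correct=0.2).pac == pytest.approx(0.2)

    def test_single_observation_nine_to_one(self):
        # Pr(O|A_c)=0.9, Pr(O|A_inc)=0.1, prior 0.5 -> 0.45/0.50 = 0.9
        model = toy_model({(1, "BP"): ([0.1, 0.9], [0.9, 0.1])})
        prof = ObservationProfile("g", [Observation(1, "BP", 1.0)])
        assert pac_for_gene(prof, model).pac == pytest.approx(0.9)

    def test_two_observations_hand_product(self):
        # (0.9 vs 0.1) and (0.8 vs 0.2): 0.36 / (0.36 + 0.01) = 0.972973
        model = toy_model({
            (1, "BP"): ([0.1, 0.9], [0.9, 0.1]),
            (2, "BP"): ([0.2, 0.8], [0.8, 0.2]),
        })
        prof = ObservationProfile(
            "g", [Observation(1, "BP", 1.0), Observation(2, "BP", 1.0)]
        )
        res = pac_for_gene(prof, model)
        assert res.n_obs == 2
        assert res.pac == pytest.approx(0.36 / 0.37, abs=1e-12)

    def test_missing_observations_are_skipped(self):
        model = toy_model({
            (1, "BP"): ([0.1, 0.9], [0.9, 0.1]),
            (2, "BP"): ([0.2, 0.8], [0.8, 0.2]),
        })
        prof = ObservationProfile(
            "g", [Observation(1, "BP", 1.0), Observation(2, "BP", None)]
        )
        assert pac_for_gene(prof, model).pac == pytest.approx(0.9)

    def test_monotone_in_single_likelihood_ratio(self):
        pacs = []
        for p in (0.2, 0.5, 0.7, 0.95):
            model = toy_model({
                (1, "BP"): ([1 - p, p], [p, 1 - p]),
                (2, "BP"): ([0.4, 0.6], [0.6, 0.4]),
            })
            prof = ObservationProfile(
                "g", [Observation(1, "BP", 1.0), Observation(2, "BP", 1.0)]
            )
            pacs.append(pac_for_gene(prof, model).pac)
        assert pacs == sorted(pacs)

    def test_posterior_complement_sums_to_one(self, small_study, default_fit):
        """Pr(A_c|O) + Pr(A_inc|O) = 1 when the complement is computed the
        same way with hypotheses and prior swapped."""
        model = default_fit.likelihoods
        swapped = LikelihoodModel(
            model.scheme, model.pseudocount, model.mode,
            {"correct": model.tables["incorrect"],
             "incorrect": model.tables["correct"]},
            {"correct": model.counts["incorrect"],
             "incorrect": model.counts["correct"]},
        )
        from pacscore import SimilarityScorer, build_profiles

        scorer = default_fit.scorer
        profiles = build_profiles(
            default_fit.model.genome, default_fit.filtered_annotations, scorer
        )
        for prof in profiles:
            a = pac_for_gene(prof, model, 0.5)
            b = pac_for_gene(prof, swapped, 0.5)
            if a.pac is None:
                assert b.pac is None
            else:
                assert abs(a.pac + b.pac - 1.0) <= 1e-12

    def test_prior_outside_unit_interval_rejected(self):
        model = toy_model({(1, "BP"): ([0.5, 0.5], [0.5, 0.5])})
        prof = ObservationProfile("g", [Observation(1, "BP", 1.0)])
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                pac_for_gene(prof, model, prior_correct=bad)


class TestPacDependent:
    def _marginal(self):
        return toy_model({
            (1, "BP"): ([0.1, 0.9], [0.9, 0.1]),
            (2, "BP"): ([0.2, 0.8], [0.8, 0.2]),
            (3, "BP"): ([0.3, 0.7], [0.7, 0.3]),
        })

    def test_degenerate_chain_equals_independent(self):
        marginal = self._marginal()
        conditionals = {
            hyp: {
                key: np.tile(marginal.tables[hyp][key], (2, 1))
                for key in marginal.tables[hyp]
                if abs(key[0]) > 1
            }
            for hyp in ("correct", "incorrect")
        }
        chain = ChainLikelihoodModel(marginal, conditionals)
        prof = ObservationProfile("g", [
            Observation(1, "BP", 1.0),
            Observation(2, "BP", 1.0),
            Observation(3, "BP", 1.0),
        ])
        assert pac_dependent(prof, chain).pac == pytest.approx(
            pac_for_gene(prof, marginal).pac, abs=1e-12
        )

    def test_single_observation_matches_independent(self):
        chain = ChainLikelihoodModel(self._marginal(), {"correct": {}, "incorrect": {}})
        prof = ObservationProfile("g", [Observation(1, "BP", 1.0)])
        assert pac_dependent(prof, chain).pac == pytest.approx(0.9)

    def test_three_observation_chain_hand_arithmetic(self):
        marginal = self._marginal()
        # conditional rows: [P(bin0 | cond bin), P(bin1 | cond bin)]
        cond_c = {
            (2, "BP"): np.array([[0.6, 0.4], [0.1, 0.9]]),
            (3, "BP"): np.array([[0.5, 0.5], [0.3, 0.7]]),
        }
        cond_i = {
            (2, "BP"): np.array([[0.4, 0.6], [0.8, 0.2]]),
            (3, "BP"): np.array([[0.5, 0.5], [0.9, 0.1]]),
        }
        chain = ChainLikelihoodModel(marginal, {"correct": cond_c, "incorrect": cond_i})
        prof = ObservationProfile("g", [
            Observation(1, "BP", 1.0),   # bin 1
            Observation(2, "BP", 1.0),   # bin 1, conditioned on O_1 bin 1
            Observation(3, "BP", 0.0),   # bin 0, conditioned on O_2 bin 1
        ])
        num = 0.5 * 0.9 * 0.9 * 0.3
        den = num + 0.5 * 0.1 * 0.2 * 0.9
        assert pac_dependent(prof, chain).pac == pytest.approx(num / den, abs=1e-12)

    def test_missing_conditioner_falls_back_to_marginal(self):
        marginal = self._marginal()
        cond = {
            "correct": {(2, "BP"): np.array([[0.6, 0.4], [0.1, 0.9]])},
            "incorrect": {(2, "BP"): np.array([[0.4, 0.6], [0.8, 0.2]])},
        }
        chain = ChainLikelihoodModel(marginal, cond)
        prof = ObservationProfile("g", [
            Observation(1, "BP", None),  # conditioner MISSING
            Observation(2, "BP", 1.0),
        ])
        # O_2 falls back to its marginal (0.8 vs 0.2)
        assert pac_dependent(prof, chain).pac == pytest.approx(0.8)


class TestGenomeScore:
    def _score(self, n_top, n_rest, filler=0.5):
        results = [PacResult(f"t{i}", 0.96, 1) for i in range(n_top)]
        results += [PacResult(f"r{i}", filler, 1) for i in range(n_rest)]
        return GenomeScore(results)

    @pytest.mark.parametrize(
        "n_top, n_eligible, printed",
        [
            (1021, 3117, 0.33),   # well-studied enterobacterium, given annotation
            (49, 3117, 0.016),    # same genome, randomized annotation
            (403, 1671, 0.24),    # distant thermophile, newer annotation
            (349, 1582, 0.22),    # distant thermophile, older annotation
        ],
    )
    def test_aqs_reproduces_printed_ratios(self, n_top, n_eligible, printed):
        score = self._score(n_top, n_eligible - n_top)
        assert score.aqs == pytest.approx(n_top / n_eligible)
        decimals = len(str(printed).split(".")[1])
        assert round(score.aqs, decimals) == printed

    def test_all_high_pac_gives_aqs_one(self):
        score = self._score(10, 0)
        assert score.aqs == 1.0

    def test_histogram_bin_conventions(self):
        score = GenomeScore([
            PacResult("a", 0.95, 1),    # closed last bin
            PacResult("b", 1.0, 1),
            PacResult("c", 0.9499, 1),  # [0.90, 0.95)
            PacResult("d", 0.0, 1),     # first bin
            PacResult("e", None, 0),    # ineligible
        ])
        assert score.n_eligible == 4
        assert score.bin_counts[-1] == 2
        assert score.bin_counts[-2] == 1
        assert score.bin_counts[0] == 1
        assert score.aqs == pytest.approx(0.5)

    def test_no_eligible_genes_gives_nan_aqs(self):
        score = GenomeScore([PacResult("a", None, 0)])
        assert math.isnan(score.aqs)

    def test_tsv_leaves_ineligible_pac_empty(self, tmp_path):
        score = GenomeScore([PacResult("a", 0.5, 2), PacResult("b", None, 0)])
        path = tmp_path / "pac.tsv"
        score.to_tsv(str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "gene_id\tn_obs\tpac"
        assert lines[2] == "b\t0\t"


class TestCalibrationCurve:
    def test_hand_tallied_fractions(self):
        correct = GenomeScore([
            PacResult("c1", 0.02, 1), PacResult("c2", 0.97, 1),
            PacResult("c3", 0.98, 1), PacResult("c4", 0.52, 1),
        ])
        random = GenomeScore([
            PacResult("r1", 0.03, 1), PacResult("r2", 0.04, 1),
            PacResult("r3", 0.96, 1), PacResult("r4", 0.51, 1),
        ])
        cal = calibration_curve(correct, random)
        first = cal.iloc[0]
        assert first.n_correct == 1 and first.n_incorrect == 2
        assert first.fraction_correct == pytest.approx(1 / 3)
        mid = cal[cal.bin_right_end == 0.55].iloc[0]
        assert mid.fraction_correct == pytest.approx(0.5)
        top = cal.iloc[-1]
        assert top.n_correct == 2 and top.n_incorrect == 1
        assert top.fraction_correct == pytest.approx(2 / 3)

    def test_pure_bins_and_empty_bins(self):
        correct = GenomeScore([PacResult("c", 0.99, 1)])
        random = GenomeScore([PacResult("r", 0.01, 1)])
        cal = calibration_curve(correct, random)
        assert cal.iloc[-1].fraction_correct == 1.0
        assert cal.iloc[0].fraction_correct == 0.0
        assert cal.fraction_correct.isna().sum() == 18  # untouched bins empty
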