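import numpy as np
import pytest

from tgskit import reference
from tgskit.genotype_model import Cohort, one_hot_encode
from tgskit.lr_scores import (
    FitConfig,
    class_probability,
    committee_scores,
    cross_validate,
    derive_score_table,
    fit_pairwise,
    vote_of,
)
from tgskit.simulate import GroupSpec, SimCohortConfig, simulate_cohort

from conftest import make_profile

#: committee scores expected from the bundled coefficients (replayed rule)
EXPECTED_DERIVED = {
    ("ACE", "DD"): 0.4165, ("ACE", "ID"): 0.0, ("ACE", "II"): -0.4655,
    ("ACTN3", "RR"): -0.0595, ("ACTN3", "RX"): 0.265, ("ACTN3", "XX"): -0.1205,
    ("MB", "AA"): 0.1025, ("MB", "AG"): 0.159, ("MB", "GG"): -0.2525,
    ("AMPD1", "CC"): 0.255, ("AMPD1", "CT"): 0.0, ("AMPD1", "TT"): -0.4005,
}


class TestClassProbability:
    @pytest.mark.parametrize("b, expected", [
        (0.0, 0.5),
        (0.415, 0.602),   # single-genotype endurance-vs-power coefficient
        (0.65, 0.657),    # worked linear-combination example
    ])
    def test_sigmoid_values(self, b, expected):
        assert class_probability(b) == pytest.approx(expected, abs=5e-4)

    def test_strictly_increasing(self):
        bs = np.linspace(-5, 5, 101)
        ps = [class_probability(b) for b in bs]
        assert all(p1 < p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(0 < p < 1 for p in ps)


class TestVoteOf:
    @pytest.mark.parametrize("b, pair, expected", [
        (-0.610, ("End", "Pow"), "Pow"),
        (0.321, ("Pow", "Mix"), "Pow"),
        (0.415, ("End", "Pow"), "End"),
        (-0.044, ("End", "Mix"), "Mix"),
        (0.0, ("End", "Pow"), "abstain"),
    ])
    def test_sign_determines_vote(self, b, pair, expected):
        assert vote_of(b, pair) == expected

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            vote_of(0.5, ("End", "End"))

    def test_vote_agrees_with_class_probability(self, reference_fits):
        for fit in reference_fits:
            for key, b in fit.coefficients.items():
                vote = vote_of(b, fit.pair)
                assert (vote == fit.class1_label) == (class_probability(b) > 0.5)


class TestCommittee:
    def test_replays_reference_scores(self, reference_fits, study_panel):
        table, decisions = committee_scores(*reference_fits, study_panel)
        for (gene, gt), expected in EXPECTED_DERIVED.items():
            assert table.score(gene, gt) == pytest.approx(expected, abs=1e-12), (gene, gt)
        by_key = {(d.gene, d.genotype): d for d in decisions}
        assert by_key[("ACE", "DD")].votes == ("End", "End", "Mix")
        assert by_key[("AMPD1", "TT")].votes == ("Pow", "End", "Pow")

    def test_signed_mean_mode_scores_mixed_majorities(self, reference_fits, study_panel):
        table, _ = committee_scores(*reference_fits, study_panel, mixed_mode="signed_mean")
        # mean of the two mixed-supporting coefficients (-0.044, -0.250)
        assert table.score("ACE", "ID") == pytest.approx(-0.147, abs=1e-12)
        assert table.score("AMPD1", "CT") == pytest.approx(np.mean([-0.453, -0.403]), abs=1e-12)

    def test_sign_consistency_with_majority(self, reference_fits, study_panel):
        _, decisions = committee_scores(*reference_fits, study_panel)
        for d in decisions:
            if d.score > 0:
                assert d.winning_trait == "End"
            elif d.score < 0:
                assert d.winning_trait == "Pow"
            if d.winning_trait in ("End", "Pow"):
                assert abs(d.score) == pytest.approx(np.mean(d.supporting_magnitudes))
            else:
                assert d.score == 0.0

    def test_three_way_split_is_tie_scored_zero(self, study_panel, reference_fits):
        import copy
        fits = [copy.deepcopy(f) for f in reference_fits]
        key = ("ACE", "DD")
        for f, b in zip(fits, (0.4, -0.3, -0.2)):  # votes End, Mix, Mix -> flip middle
            f.coefficients[key] = b
        fits[1].coefficients[key] = -0.3   # E_vs_M: Mix
        fits[2].coefficients[key] = 0.2    # P_vs_M: Pow -> End/Mix/Pow split
        with pytest.warns(UserWarning, match="majority"):
            table, decisions = committee_scores(*fits, study_panel)
        d = next(d for d in decisions if (d.gene, d.genotype) == key)
        assert d.winning_trait == "tie"
        assert table.score(*key) == 0.0

    def test_mismatched_panels_rejected(self, reference_fits, study_panel):
        import copy
        fits = [copy.deepcopy(f) for f in reference_fits]
        del fits[2].coefficients[("ACE", "DD")]
        with pytest.raises(ValueError, match="panel"):
            committee_scores(*fits, study_panel)


def two_group_cohort(panel, dist_a, dist_b, n=200, seed=0):
    config = SimCohortConfig(panel, (
        GroupSpec("endurance", n, {m.gene: dist_a for m in panel}),
        GroupSpec("power", n, {m.gene: dist_b for m in panel}),
    ), seed=seed)
    return simulate_cohort(config)


class TestFitPairwise:
    def test_perfectly_associated_genotype_gets_positive_coefficient(self, toy_panel):
        cohort = two_group_cohort(toy_panel, (1.0, 0.0, 0.0), (0.0, 0.5, 0.5), n=100)
        enc = one_hot_encode(cohort)
        y = np.array([1 if p.group == "endurance" else 0 for p in cohort.profiles])
        fit = fit_pairwise(enc, y, "End", "Pow")
        assert fit.coefficients[("ACE", "DD")] > 0.5
        assert fit.class_probabilities[("ACE", "DD")] > 0.5

    def test_unobserved_genotype_column_shrunk_to_zero(self, toy_panel):
        # II never occurs -> its all-zero column has no signal, only penalty
        cohort = two_group_cohort(toy_panel, (0.6, 0.4, 0.0), (0.4, 0.6, 0.0), n=100)
        enc = one_hot_encode(cohort)
        y = np.array([1 if p.group == "endurance" else 0 for p in cohort.profiles])
        fit = fit_pairwise(enc, y, "End", "Pow")
        assert abs(fit.coefficients[("ACE", "II")]) < 1e-2

    def test_single_class_rejected(self, toy_panel):
        cohort = two_group_cohort(toy_panel, (1, 0, 0), (1, 0, 0), n=10)
        enc = one_hot_encode(cohort)
        with pytest.raises(ValueError, match="2 classes"):
            fit_pairwise(enc, np.ones(len(cohort), dtype=int), "End", "Pow")


class TestCrossValidate:
    def test_separable_data_has_high_accuracy(self, toy_panel):
        cohort = two_group_cohort(toy_panel, (1, 0, 0), (0, 0, 1), n=100, seed=1)
        enc = one_hot_encode(cohort)
        y = np.array([1 if p.group == "endurance" else 0 for p in cohort.profiles])
        report = cross_validate(enc, y, FitConfig(seed=1))
        assert report.mean >= 0.95
        assert report.confusion.sum() == 200

    def test_random_labels_near_chance(self, toy_panel):
        cohort = two_group_cohort(toy_panel, (1 / 3, 1 / 3, 1 / 3), (1 / 3, 1 / 3, 1 / 3),
                                  n=100, seed=2)
        enc = one_hot_encode(cohort)
        rng = np.random.default_rng(3)
        y = rng.permutation(np.repeat([0, 1], 100))
        report = cross_validate(enc, y, FitConfig(seed=3))
        assert 0.35 <= report.mean <= 0.65
        assert report.confusion.sum() == 200

    def test_class_smaller_than_fold_count_rejected(self, toy_panel):
        cohort = two_group_cohort(toy_panel, (1, 0, 0), (0, 1, 0), n=4)
        enc = one_hot_encode(cohort)
        y = np.array([1 if p.group == "endurance" else 0 for p in cohort.profiles])
        with pytest.raises(ValueError, match="fold"):
            cross_validate(enc, y, FitConfig(cv_folds=10))


class TestDeriveScoreTable:
    def test_planted_endurance_genotype_scores_positive(self, toy_panel):
        config = SimCohortConfig(toy_panel, (
            GroupSpec("endurance", 400, {"ACE": (0.6, 0.2, 0.2)}),
            GroupSpec("mixed", 400, {"ACE": (0.2, 0.6, 0.2)}),
            GroupSpec("power", 400, {"ACE": (0.2, 0.2, 0.6)}),
        ), seed=11)
        cohort = simulate_cohort(config)
        table, decisions, fits = derive_score_table(cohort, FitConfig(seed=11))
        assert table.score("ACE", "DD") > 0
        assert table.score("ACE", "II") < 0
        assert set(fits) == {"E_vs_P", "E_vs_M", "P_vs_M"}

    def test_unmappable_group_label_rejected(self, toy_panel):
        cohort = two_group_cohort(toy_panel, (1, 0, 0), (0, 1, 0), n=20)
        cohort.profiles[0].group = "sprinters"
        cohort = Cohort(cohort.panel, cohort.profiles)
        with pytest.raises(ValueError, match="trait_map"):
            derive_score_table(cohort)
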