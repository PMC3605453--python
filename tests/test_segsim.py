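"""Segregation-error simulators against exact combinatorial oracles."""

import numpy as np
import pytest

from karyolute.profiles import CopyNumberProfile, KaryotypeRecord
from karyolute.segsim import (
    SegregationModel,
    SimulationConfig,
    chisq_compare,
    evolve_to_target,
    evolve_to_target_copies,
    expected_prevalence,
    pooled_cn_distribution,
    run_cohort_evaluation,
    tripolar_amphitelic_division,
    tripolar_random_division,
)
from oracles import enumerate_loss_distribution, loss_profile_probability, pearson_chisq

LOSS = SegregationModel("loss_from_tetraploidy")


def profile(counts):
    return CopyNumberProfile.from_counts(counts)


class TestModelValidation:
    def test_loss_requires_tetraploid_start(self):
        with pytest.raises(ValueError):
            SegregationModel("loss_from_tetraploidy", "diploid")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            SegregationModel("mitotic_chaos")

    def test_unreachable_target_is_argument_error(self):
        with pytest.raises(ValueError, match="unreachable"):
            evolve_to_target_copies(LOSS, 93, SimulationConfig(n_virtual=10))
        with pytest.raises(ValueError, match="unreachable"):
            evolve_to_target_copies(LOSS, 22, SimulationConfig(n_virtual=10))


class TestLossFromTetraploidy:
    def test_zero_steps_all_tetrasomic(self):
        profs = evolve_to_target(LOSS, 92, SimulationConfig(n_virtual=50, seed=1))
        assert all(p.counts == {4: 23} for p in profs)

    def test_single_forced_loss(self):
        profs = evolve_to_target(LOSS, 91, SimulationConfig(n_virtual=50, seed=1))
        assert all(p.counts == {4: 22, 3: 1} for p in profs)

    def test_two_step_mixture_matches_enumeration(self):
        # P(second loss hits the first chromosome again) = 3/91
        dist = enumerate_loss_distribution(2)
        twice = tuple(sorted([2] + [4] * 22))
        assert dist[twice] == pytest.approx(3 / 91)
        cfg = SimulationConfig(n_virtual=40_000, seed=7)
        copies = evolve_to_target_copies(LOSS, 90, cfg)
        prev = expected_prevalence(profile({4: 22, 2: 1}), copies)
        se = np.sqrt(3 / 91 * (1 - 3 / 91) / cfg.n_virtual)
        assert abs(prev - 3 / 91) < 3 * se

    @pytest.mark.parametrize("n_steps", [1, 2, 3])
    def test_enumeration_agrees_with_subset_combinatorics(self, n_steps):
        # two independent oracles for the same distribution
        from collections import Counter

        for copies_key, p in enumerate_loss_distribution(n_steps).items():
            assert float(p) == pytest.approx(
                float(loss_profile_probability(dict(Counter(copies_key)))), abs=1e-12
            )

    def test_three_step_prevalences_match_enumeration(self):
        dist = enumerate_loss_distribution(3)
        cfg = SimulationConfig(n_virtual=40_000, seed=11)
        copies = evolve_to_target_copies(LOSS, 89, cfg)
        for key, p in dist.items():
            prev = expected_prevalence(CopyNumberProfile.from_copies(key), copies)
            se = np.sqrt(float(p) * (1 - float(p)) / cfg.n_virtual)
            assert abs(prev - float(p)) < 4 * se + 1e-12

    def test_deep_loss_matches_exact_oracle(self):
        # reference stem line: 49 chromosomes, monosomy 1, trisomies 2 and 3,
        # tetrasomy 4 — a rare profile deep in the loss process
        obs = profile({1: 1, 2: 19, 3: 2, 4: 1})
        exact = float(loss_profile_probability(obs.counts))
        cfg = SimulationConfig(n_virtual=60_000, seed=13)
        copies = evolve_to_target_copies(LOSS, 49, cfg)
        prev = expected_prevalence(obs, copies)
        # nullisomy replacement duplicates survivors (~31% survive at N=49),
        # so use the effective unique-survivor sample size for the MC error
        n_eff = 0.3 * cfg.n_virtual
        se = np.sqrt(exact * (1 - exact) / n_eff)
        assert abs(prev - exact) < 4 * se

    def test_monosomy_selection_removes_monosomies(self):
        cfg = SimulationConfig(n_virtual=5_000, seed=3, monosomy_selection=True)
        copies = evolve_to_target_copies(LOSS, 60, cfg)
        assert copies.min() >= 2
        assert (copies.sum(axis=1) == 60).all()

    def test_monosomy_selection_matches_conditioned_oracle(self):
        cfg = SimulationConfig(n_virtual=40_000, seed=5, monosomy_selection=True)
        copies = evolve_to_target_copies(LOSS, 85, cfg)
        obs = profile({4: 17, 3: 5, 2: 1})
        exact = float(loss_profile_probability(obs.counts, monosomy_selection=True))
        prev = expected_prevalence(obs, copies)
        se = np.sqrt(exact * (1 - exact) / (0.5 * cfg.n_virtual))
        assert abs(prev - exact) < 4 * se


class TestSeqNondisjunction:
    def test_upward_steps_from_diploid(self):
        model = SegregationModel("seq_nondisjunction", "diploid")
        copies = evolve_to_target_copies(model, 49, SimulationConfig(n_virtual=500, seed=2))
        assert (copies.sum(axis=1) == 49).all()
        assert copies.min() >= 2  # gains only: no chromosome below disomy
        assert ((copies - 2).sum(axis=1) == 3).all()

    def test_downward_steps_from_tetraploid(self):
        model = SegregationModel("seq_nondisjunction", "tetraploid")
        copies = evolve_to_target_copies(model, 80, SimulationConfig(n_virtual=500, seed=2))
        assert (copies.sum(axis=1) == 80).all()
        assert copies.min() >= 1 and copies.max() <= 4


class TestTripolarDivisions:
    def test_random_division_conserves_chromatids(self, rng):
        parent = rng.integers(1, 6, size=23)
        daughters = tripolar_random_division(parent, rng)
        assert daughters.shape == (3, 23)
        assert (daughters.sum(axis=0) == 2 * parent).all()

    def test_amphitelic_division_one_gains_one_loses(self, rng):
        parent = np.full(23, 4)
        gains, losses = tripolar_amphitelic_division(parent, rng)
        assert (gains + losses == 2 * parent).all()
        assert (gains >= parent).all() and (losses <= parent).all()

    def test_random_evolution_hits_target_viably(self):
        model = SegregationModel("tripolar_random", "tetraploid")
        copies = evolve_to_target_copies(model, 60, SimulationConfig(n_virtual=300, seed=4))
        assert (copies.sum(axis=1) == 60).all()
        assert copies.min() >= 1

    def test_amphitelic_gains_side_from_diploid(self):
        model = SegregationModel("tripolar_amphitelic_cytofail", "diploid")
        copies = evolve_to_target_copies(model, 60, SimulationConfig(n_virtual=300, seed=4))
        assert (copies.sum(axis=1) == 60).all()
        assert copies.min() >= 2  # gains daughter never drops below parent copies

    def test_amphitelic_losses_side_binomial_marginal(self):
        # losses-daughter copy numbers follow Binomial(4, 2/3) per type,
        # conditioned on the target total
        model = SegregationModel("tripolar_amphitelic_cytofail", "tetraploid")
        copies = evolve_to_target_copies(model, 61, SimulationConfig(n_virtual=2000, seed=9))
        assert copies.max() <= 4
        assert abs(copies.mean() - 61 / 23) < 1e-9


class TestExpectedPrevalence:
    def test_trivial_certainty(self):
        copies = evolve_to_target_copies(LOSS, 91, SimulationConfig(n_virtual=20, seed=1))
        assert expected_prevalence(profile({4: 22, 3: 1}), copies) == 1.0

    def test_chromosome_identity_ignored(self):
        sim = np.array([[3, 2, 2], [2, 2, 3]])
        obs = CopyNumberProfile.from_copies([2, 3, 2])
        assert expected_prevalence(obs, sim) == 1.0

    def test_n_mismatch_rejected(self):
        copies = evolve_to_target_copies(LOSS, 91, SimulationConfig(n_virtual=10, seed=1))
        with pytest.raises(ValueError, match="N=90"):
            expected_prevalence(profile({4: 21, 3: 2}), copies)

    def test_empty_simulation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expected_prevalence(profile({4: 23}), [])


class TestPooledDistribution:
    def test_single_profile(self):
        assert pooled_cn_distribution([profile({2: 23})]) == {2: 1.0}

    def test_two_profiles(self):
        d = pooled_cn_distribution([profile({2: 23}), profile({3: 23})])
        assert d == {2: 0.5, 3: 0.5}

    def test_matches_weighted_mean_of_per_case_distributions(self, rng):
        profs = [
            CopyNumberProfile.from_copies(rng.integers(1, 5, size=23))
            for _ in range(7)
        ]
        pooled = pooled_cn_distribution(profs)
        classes = sorted(pooled)
        per_case = np.array(
            [[p.count(k) / 23 for k in classes] for p in profs]
        )
        assert np.allclose([pooled[k] for k in classes], per_case.mean(axis=0))
        assert sum(pooled.values()) == pytest.approx(1.0)


class TestChisqCompare:
    def test_proportional_gives_zero_statistic(self):
        res = chisq_compare({1: 10, 2: 10}, {1: 0.5, 2: 0.5})
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_textbook_four_category_statistic(self):
        obs = {1: 10, 2: 20, 3: 30, 4: 40}
        exp = {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}
        res = chisq_compare(obs, exp)
        assert res.statistic == pytest.approx(
            pearson_chisq([10, 20, 30, 40], [25, 25, 25, 25])
        )
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 3

    def test_sparse_classes_pooled(self):
        res = chisq_compare(
            {1: 1, 2: 50, 3: 49}, {1: 0.01, 2: 0.5, 3: 0.49}, min_expected=5
        )
        assert res.df == 1  # class 1 pooled into class 2

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            chisq_compare({1: 0, 2: 0}, {1: 0.5, 2: 0.5})


class TestCohortEvaluation:
    def test_single_forced_case_has_certain_prevalence(self):
        cohort = [KaryotypeRecord("c1", profile({4: 22, 3: 1}))]
        ev = run_cohort_evaluation(cohort, LOSS, SimulationConfig(n_virtual=200, seed=1))
        assert ev.mean_prevalence == 1.0
        assert ev.per_case.loc[0, "flag"] == ""

    def test_unreachable_case_flagged_not_fatal(self):
        cohort = [
            KaryotypeRecord("ok", profile({4: 22, 3: 1})),
            KaryotypeRecord("too_big", profile({4: 22, 5: 1})),  # N=93 > 92
        ]
        ev = run_cohort_evaluation(cohort, LOSS, SimulationConfig(n_virtual=100, seed=1))
        flags = dict(zip(ev.per_case["case_id"], ev.per_case["flag"]))
        assert flags["too_big"] == "unreachable"
        assert ev.per_case["expected_prevalence"].tolist() == [1.0, 0.0]

    def test_seeded_runs_bit_reproducible(self):
        cohort = [KaryotypeRecord("c", profile({4: 10, 3: 8, 2: 5}))]
        cfg = SimulationConfig(n_virtual=400, seed=42)
        a = run_cohort_evaluation(cohort, LOSS, cfg)
        b = run_cohort_evaluation(cohort, LOSS, cfg)
        assert a.per_case.equals(b.per_case)
        assert a.pooled_expected == b.pooled_expected


class TestEmittedPopulationInvariants:
    @pytest.mark.parametrize(
        "model,target",
        [
            (LOSS, 55),
            (SegregationModel("seq_nondisjunction", "diploid"), 55),
            # monosomies are near-universal in randomised tripolar daughters at
            # low totals; 75 leaves a workable monosomy-free pool
            (SegregationModel("tripolar_random", "tetraploid"), 75),
            (SegregationModel("tripolar_amphitelic_cytofail", "tetraploid"), 60),
        ],
    )
    def test_no_nullisomy_and_exact_target(self, model, target):
        cfg = SimulationConfig(n_virtual=500, seed=8)
        copies = evolve_to_target_copies(model, target, cfg)
        assert (copies.sum(axis=1) == target).all()
        assert copies.min() >= 1
        sel = SimulationConfig(n_virtual=500, seed=8, monosomy_selection=True)
        copies = evolve_to_target_copies(model, target, sel)
        assert copies.min() >= 2
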