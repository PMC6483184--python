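"""Interaction kernel: utterance sampling, learning update, rounds, entry rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from langshift import (
    LearningParams,
    Population,
    apply_update,
    expected_round_change,
    init_newborn,
    init_recruit,
    interaction_round,
    mutate_to_novel,
    population_mean,
    utter,
)
from langshift.core import SpeakerClass


class TestApplyUpdate:
    @pytest.mark.parametrize(
        "usage, heard, l, expected",
        [
            ((0.5, 0.5), 2, 0.1, (0.45, 0.55)),
            ((0.25, 0.75), 1, 0.0, (0.25, 0.75)),  # l = 0 is the identity
            ((0.3, 0.7), 1, 1.0, (1.0, 0.0)),  # full adoption at l = 1
            ((0.2, 0.3, 0.5), 3, 0.1, (0.18, 0.27, 0.55)),
        ],
    )
    def test_examples(self, usage, heard, l, expected):
        out = apply_update(np.array(usage), heard, l)
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_invalid_learning_weight_rejected(self):
        with pytest.raises(ValueError):
            apply_update(np.array([0.5, 0.5]), 1, 1.5)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            apply_update(np.array([0.7, 0.7]), 1, 0.1)
        with pytest.raises(ValueError):
            apply_update(np.array([-0.1, 1.1]), 1, 0.1)

    @given(
        p=st.floats(0.0, 1.0),
        l=st.floats(0.0, 1.0),
        heard=st.integers(1, 2),
    )
    @settings(derandomize=True, max_examples=200)
    def test_conservation_and_monotonicity(self, p, l, heard):
        """The update conserves total mass; the heard variant never loses
        probability and the unheard one never gains."""
        usage = np.array([p, 1.0 - p])
        out = apply_update(usage, heard, l)
        assert abs(out.sum() - 1.0) < 1e-12
        assert out[heard - 1] >= usage[heard - 1] - 1e-15
        other = 2 - heard
        assert out[other] <= usage[other] + 1e-15


class TestUtter:
    def test_degenerate_distributions(self, rng):
        assert all(utter(np.array([1.0, 0.0]), rng) == 1 for _ in range(20))
        assert all(utter(np.array([0.0, 1.0]), rng) == 2 for _ in range(20))

    def test_balanced_frequency(self, rng):
        n = 100_000
        draws = sum(utter(np.array([0.5, 0.5]), rng) == 2 for _ in range(n))
        se = 0.5 / np.sqrt(n)
        assert abs(draws / n - 0.5) < 3 * se

    def test_invalid_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            utter(np.array([0.6, 0.6]), rng)


def _two_agent_population(pa, pb):
    return Population(
        np.array([pa, pb]),
        np.array([SpeakerClass.L1.value] * 2),
        np.zeros(2, dtype=int),
    )


class TestInteractionRound:
    def test_homogeneous_population_is_fixed_point(self, rng):
        pop = _two_agent_population([1.0, 0.0], [1.0, 0.0])
        interaction_round(pop, LearningParams(l=0.05), rng)
        np.testing.assert_array_equal(pop.probs, [[1, 0], [1, 0]])

    def test_forced_utterances(self, rng):
        """Opposite pure speakers must exchange exactly l of probability."""
        pop = _two_agent_population([1.0, 0.0], [0.0, 1.0])
        interaction_round(pop, LearningParams(l=0.05), rng)
        got = {tuple(np.round(row, 10)) for row in pop.probs}
        assert got == {(0.95, 0.05), (0.05, 0.95)}

    def test_too_small_population_rejected(self, rng):
        pop = Population(np.array([[1.0, 0.0]]), np.array([1]), np.array([0]))
        with pytest.raises(ValueError):
            interaction_round(pop, LearningParams(), rng)

    def test_odd_population_leaves_one_agent_idle(self, rng):
        probs = np.array([[0.3, 0.7], [0.6, 0.4], [0.2, 0.8]])
        pop = Population(probs.copy(), np.ones(3, dtype=int), np.zeros(3, dtype=int))
        interaction_round(pop, LearningParams(l=0.5), rng)
        unchanged = sum(np.array_equal(pop.probs[i], probs[i]) for i in range(3))
        assert unchanged == 1  # interior rows always move when they update

    def test_identical_seeds_bitwise_identical(self):
        p = np.random.default_rng(3).dirichlet((1, 1), 6)
        runs = []
        for _ in range(2):
            pop = Population(p.copy(), np.ones(6, dtype=int), np.zeros(6, dtype=int))
            rng = np.random.default_rng(99)
            for _ in range(50):
                interaction_round(pop, LearningParams(l=0.1), rng)
            runs.append(pop.probs.copy())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestNeutrality:
    @pytest.mark.parametrize("n_agents", [2, 4])
    @pytest.mark.parametrize("l", [0.05, 0.37, 1.0])
    def test_expected_mean_change_is_zero(self, n_agents, l):
        """Exact enumeration over matchings and utterance outcomes: the
        interaction dynamics favour no variant."""
        probs = np.random.default_rng(7).dirichlet((1.3, 0.7), n_agents)
        delta = expected_round_change(probs, l)
        assert np.abs(delta).max() < 1e-12

    def test_three_variant_neutrality(self):
        probs = np.random.default_rng(11).dirichlet((1, 1, 1), 2)
        delta = expected_round_change(probs, 0.2)
        assert np.abs(delta).max() < 1e-12


class TestPopulationMean:
    def test_examples(self):
        pop = Population(
            np.array([[1.0, 0.0], [1.0, 0.0], [0.4, 0.6]]),
            np.ones(3, dtype=int),
            np.zeros(3, dtype=int),
        )
        np.testing.assert_allclose(population_mean(pop), [0.8, 0.2])

    def test_empty_population_rejected(self):
        pop = Population(
            np.empty((0, 2)), np.empty(0, dtype=int), np.empty(0, dtype=int)
        )
        with pytest.raises(ValueError):
            population_mean(pop)


class TestEntryRules:
    def test_newborn_averages_parents(self):
        np.testing.assert_allclose(
            init_newborn(np.array([1.0, 0.0]), np.array([0.0, 1.0])), [0.5, 0.5]
        )
        np.testing.assert_allclose(
            init_newborn(np.array([0.2, 0.8]), np.array([0.6, 0.4])), [0.4, 0.6]
        )
        p = np.array([0.35, 0.65])
        np.testing.assert_allclose(init_newborn(p, p), p)  # idempotent

    def test_recruit_without_innovation_copies_mean(self, rng):
        usage, innovated = init_recruit(
            np.array([0.8, 0.2]), LearningParams(mu=0.0), rng
        )
        assert not innovated
        np.testing.assert_allclose(usage, [0.8, 0.2])

    def test_recruit_with_certain_innovation(self, rng):
        usage, innovated = init_recruit(
            np.array([1.0, 0.0]), LearningParams(mu=1.0), rng
        )
        assert innovated
        np.testing.assert_array_equal(usage, [0.0, 1.0])

    def test_innovation_frequency_binomial_bound(self, rng):
        n = 10_000
        params = LearningParams(mu=0.5)
        hits = sum(
            init_recruit(np.array([1.0, 0.0]), params, rng)[1] for _ in range(n)
        )
        se = 0.5 / np.sqrt(n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_mutate_to_novel(self):
        np.testing.assert_array_equal(
            mutate_to_novel(np.array([0.9, 0.1]), 2), [0.0, 1.0]
        )
        np.testing.assert_array_equal(
            mutate_to_novel(np.array([0.0, 1.0]), 2), [0.0, 1.0]
        )
        np.testing.assert_array_equal(
            mutate_to_novel(np.array([0.5, 0.25, 0.25]), 2), [0.0, 1.0, 0.0]
        )


class TestLearningParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            LearningParams(l=1.2)
        with pytest.raises(ValueError):
            LearningParams(mu=-0.1)
        with pytest.raises(ValueError):
            LearningParams(novel_index=1)
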