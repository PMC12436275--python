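import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paretomol import moo
from paretomol.fixtures import make_scored_batch


def brute_force_fronts(scores: np.ndarray) -> list[list[int]]:
    """O(N^2) peeling oracle: repeatedly remove the set of solutions
    dominated by nobody still present."""
    remaining = list(range(len(scores)))
    fronts = []
    while remaining:
        front = [i for i in remaining
                 if not any(moo.dominates(scores[j], scores[i])
                            for j in remaining if j != i)]
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestNormalizePx:
    @pytest.mark.parametrize("px,expected", [
        (6.5, 0.5), (4.0, 0.0), (9.0, 1.0), (11.0, 1.0), (2.0, 0.0),
    ])
    def test_fixed_range_anchors(self, px, expected):
        assert moo.normalize_px(px) == pytest.approx(expected)

    def test_monotone_nondecreasing(self):
        grid = np.linspace(0, 12, 200)
        vals = moo.normalize_px(grid)
        assert (np.diff(vals) >= 0).all()

    def test_batch_relative_mode(self):
        batch = np.array([5.0, 7.0, np.nan])
        assert moo.normalize_px(6.0, batch=batch) == pytest.approx(0.5)


class TestObjectiveReward:
    def _spec(self, direction):
        return moo.ObjectiveSpec("T", direction, predictor=lambda s: None)

    def test_invalid_molecule_scores_zero(self):
        for direction in ("high_affinity", "low_affinity"):
            assert moo.objective_reward(8.0, self._spec(direction),
                                        valid=False) == 0.0

    def test_low_affinity_mirrors(self):
        spec = self._spec("low_affinity")
        assert moo.objective_reward(9.0, spec) == pytest.approx(0.0)
        assert moo.objective_reward(4.0, spec) == pytest.approx(1.0)

    def test_threshold_symmetry(self):
        for direction in ("high_affinity", "low_affinity"):
            assert moo.objective_reward(6.5, self._spec(direction)) == \
                pytest.approx(0.5)

    def test_direction_validated(self):
        with pytest.raises(ValueError):
            self._spec("sideways")

    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            moo.ObjectiveSpec("T", "high_affinity", predictor=None,
                              threshold=1.0)


class TestWeightedScheme:
    def test_hand_computed_ratio_example(self):
        # objective 1: 20 below / 20 above -> r=1; objective 2: 30/10 -> r=3
        rewards = np.zeros((40, 2))
        rewards[:, 0] = np.r_[np.full(20, 0.4), np.full(20, 0.6)]
        rewards[:, 1] = np.r_[np.full(30, 0.4), np.full(10, 0.6)]
        alloc, _ = moo.weighted_reward(rewards)
        assert np.allclose(alloc.ratios, [1.0, 3.0])
        assert np.allclose(alloc.weights, [0.25, 0.75])

    def test_perfect_molecule_gets_unit_reward(self):
        rewards = np.vstack([np.ones(3), np.full(3, 0.2)])
        _, final = moo.weighted_reward(rewards)
        assert final[0] == pytest.approx(1.0)

    def test_single_objective_passthrough(self):
        rewards = np.array([[0.3], [0.8]])
        alloc, final = moo.weighted_reward(rewards)
        assert np.allclose(alloc.weights, [1.0])
        assert np.allclose(final, [0.3, 0.8])

    def test_all_above_threshold_falls_back_to_uniform(self):
        rewards = np.full((5, 2), 0.9)
        alloc, _ = moo.weighted_reward(rewards)
        assert np.allclose(alloc.weights, [0.5, 0.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 30), st.integers(1, 4))
    def test_weight_and_range_invariants(self, seed, n, k):
        rewards, _ = make_scored_batch(n, k, seed)
        alloc, final = moo.weighted_reward(rewards)
        assert alloc.weights.sum() == pytest.approx(1.0)
        assert (alloc.weights >= 0).all()
        assert ((final >= 0) & (final <= 1)).all()

    def test_monotone_in_each_objective(self):
        rewards, _ = make_scored_batch(20, 3, seed=5)
        alloc, final = moo.weighted_reward(rewards)
        bumped = rewards.copy()
        bumped[7, 1] = min(1.0, bumped[7, 1] + 0.2)
        # same weights applied to a raised reward can only raise R*
        assert (bumped[7] @ alloc.weights) >= final[7]


class TestClipAndDominance:
    @pytest.mark.parametrize("r,t,expected", [
        (0.8, 0.5, 1.0), (0.25, 0.5, 0.5), (0.0, 0.5, 0.0), (0.5, 0.5, 1.0),
    ])
    def test_clip_score(self, r, t, expected):
        assert moo.clip_score(r, t) == pytest.approx(expected)

    def test_dominance_cases(self):
        assert moo.dominates([0.6, 0.6, 0.6], [0.5, 0.6, 0.4])
        assert not moo.dominates([1, 1], [1, 1])
        assert not moo.dominates([1, 0], [0, 1])
        assert not moo.dominates([0, 1], [1, 0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            moo.dominates([1, 2], [1, 2, 3])


class TestNondominatedSort:
    def test_three_point_example(self):
        fronts = moo.nondominated_sort([[1, 1], [0.5, 0.5], [1, 0.2]])
        assert fronts[0] == [0]
        assert sorted(fronts[1]) == [1, 2]

    def test_identical_vectors_single_front(self):
        fronts = moo.nondominated_sort(np.full((6, 3), 0.4))
        assert len(fronts) == 1

    def test_single_molecule(self):
        assert moo.nondominated_sort([[0.2, 0.9]]) == [[0]]

    def test_fronts_partition_batch(self):
        scores, _ = make_scored_batch(60, 3, seed=1)
        fronts = moo.nondominated_sort(scores)
        flat = sorted(i for f in fronts for i in f)
        assert flat == list(range(60))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 60))
    def test_agrees_with_brute_force_oracle(self, seed, n):
        scores, _ = make_scored_batch(n, 3, seed)
        fast = moo.nondominated_sort(scores)
        oracle = brute_force_fronts(scores)
        assert [sorted(f) for f in fast] == [sorted(f) for f in oracle]


class TestFrontDistanceRank:
    def test_rank_is_permutation(self):
        rewards, fps = make_scored_batch(30, 3, seed=2)
        fronts = moo.nondominated_sort(rewards)
        order = moo.front_distance_rank(fronts, fps)
        assert sorted(order) == list(range(30))

    def test_best_front_occupies_highest_ranks(self):
        rewards, fps = make_scored_batch(25, 2, seed=3)
        fronts = moo.nondominated_sort(rewards)
        order = moo.front_distance_rank(fronts, fps)
        worst_front = fronts[-1]
        best_front = fronts[0]
        assert max(order[i] for i in worst_front) < \
            min(order[i] for i in best_front)

    def test_duplicate_structures_tie_broken_by_input_order(self):
        fronts = [[0, 1, 2]]
        fps = np.tile(np.array([1, 0, 1, 0]), (3, 1))
        order = moo.front_distance_rank(fronts, fps)
        assert list(order) == [0, 1, 2]

    def test_singleton_front_distance_zero(self):
        fronts = [[1], [0]]
        fps = np.eye(2, 8)
        order = moo.front_distance_rank(fronts, fps)
        assert order[0] == 0  # worst front first
        assert order[1] == 1


class TestParetoReward:
    def test_hand_computed_two_by_two(self):
        order = np.array([0, 1, 2, 3])
        desirable = np.array([False, False, True, True])
        final, k = moo.pareto_reward(order, desirable)
        assert np.allclose(final, [0.0, 0.25, 0.5, 0.75])

    def test_separation_property(self):
        rewards, fps = make_scored_batch(40, 3, seed=6)
        desirable = rewards.min(axis=1) >= 0.5
        if desirable.any() and (~desirable).any():
            final, _ = moo.pareto_scheme(rewards, desirable, fps)
            assert final[desirable].min() > final[~desirable].max()
            assert final[desirable].min() >= 0.5
            assert final[~desirable].max() < 0.5

    def test_all_desired_block_formula(self):
        final, _ = moo.pareto_reward(np.arange(4), np.ones(4, dtype=bool))
        assert np.allclose(final, [0.5, 0.625, 0.75, 0.875])

    def test_all_undesired_block_formula(self):
        final, _ = moo.pareto_reward(np.arange(4), np.zeros(4, dtype=bool))
        assert np.allclose(final, [0.0, 0.125, 0.25, 0.375])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 50))
    def test_rewards_bounded_and_separated(self, seed, n):
        rewards, fps = make_scored_batch(n, 3, seed)
        desirable = rewards.min(axis=1) >= 0.4
        final, ranking = moo.pareto_scheme(rewards, desirable, fps)
        assert ((final >= 0) & (final < 1)).all()
        assert ranking.n_desired + ranking.n_undesired == n
        if desirable.any():
            assert (final[desirable] >= 0.5).all()
        if (~desirable).any():
            assert (final[~desirable] < 0.5).all()


class TestTanimoto:
    def test_identical_fingerprints_distance_zero(self):
        fps = np.tile(np.array([1, 1, 0, 0]), (2, 1))
        assert moo.tanimoto_distance_matrix(fps)[0, 1] == pytest.approx(0.0)

    def test_disjoint_fingerprints_distance_one(self):
        fps = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert moo.tanimoto_distance_matrix(fps)[0, 1] == pytest.approx(1.0)
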