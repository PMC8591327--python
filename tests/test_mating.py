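import itertools

import numpy as np
import pytest

from hetocs import (
    GameteAllocation,
    MatePlan,
    contributions_to_gametes,
    expected_progeny_homozygosity,
    random_mating,
    solve_mating,
    compute_grm,
    encode_genotypes,
)

from conftest import MICRO_X, panel_from_X


def enumerate_optimal_cost(g: np.ndarray, cost: np.ndarray) -> float:
    """Exhaustive oracle: minimum cost over all integer degree-feasible plans."""
    n = len(g)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    best = [np.inf]

    def rec(k, remaining, acc):
        # no cost-based pruning: costs may be negative
        if k == len(pairs):
            if all(r == 0 for r in remaining):
                best[0] = min(best[0], acc)
            return
        i, j = pairs[k]
        # prune: remaining degree of i must be coverable by later pairs
        later = [p for p in pairs[k:] if i in p]
        if remaining[i] > sum(min(remaining[p[0]], remaining[p[1]]) for p in later):
            return
        for cnt in range(min(remaining[i], remaining[j]) + 1):
            remaining[i] -= cnt
            remaining[j] -= cnt
            rec(k + 1, remaining, acc + cnt * cost[i, j])
            remaining[i] += cnt
            remaining[j] += cnt

    rec(0, list(g), 0.0)
    return best[0]


def random_feasible_degrees(n, n_offspring, rng):
    """Degrees realized by a random plan, hence always feasible."""
    plan = np.zeros((n, n), dtype=int)
    for _ in range(n_offspring):
        i, j = rng.choice(n, size=2, replace=False)
        plan[i, j] += 1
        plan[j, i] += 1
    return plan.sum(axis=1)


class TestDiscretization:
    def test_exact_integer_contributions(self):
        g = contributions_to_gametes(np.array([0.5, 0.5]), 10)
        assert g.g.tolist() == [10, 10]
        g = contributions_to_gametes(np.array([0.5, 0.25, 0.25]), 2)
        assert g.g.tolist() == [2, 1, 1]

    def test_largest_remainder_property(self):
        c = np.array([0.4, 0.35, 0.25])
        g = contributions_to_gametes(c, 5)
        assert g.g.sum() == 10
        assert np.all(np.abs(g.g - 10 * c) < 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_rounding_error_below_one_gamete(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.dirichlet(np.ones(8))
        while c.max() > 0.5:  # resample until the no-selfing cap is met
            c = rng.dirichlet(np.ones(8))
        n_off = int(rng.integers(3, 30))
        g = contributions_to_gametes(c, n_off)
        assert g.g.sum() == 2 * n_off
        assert np.all(np.abs(g.g - 2 * n_off * c) <= 1.0 + 1e-9)
        assert np.all(g.g <= n_off)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            contributions_to_gametes(np.array([0.5, 0.5]), 0)
        with pytest.raises(ValueError):
            contributions_to_gametes(np.array([0.7, 0.3]), 5)


class TestSolveMating:
    def test_unique_feasible_plan(self):
        # g = (2,1,1): {AB:1, AC:1} is the only degree-feasible plan
        rng = np.random.default_rng(0)
        for _ in range(5):
            cost = rng.normal(size=(3, 3))
            cost = (cost + cost.T) / 2
            plan = solve_mating(GameteAllocation(np.array([2, 1, 1]), 2), cost)
            assert plan.pairs() == [(0, 1, 1), (0, 2, 1)]

    def test_picks_cheapest_perfect_matching(self):
        cost = np.full((4, 4), 10.0)
        np.fill_diagonal(cost, 0.0)
        cost[0, 1] = cost[1, 0] = 1.0
        cost[2, 3] = cost[3, 2] = 1.0
        plan = solve_mating(GameteAllocation(np.ones(4, dtype=int), 2), cost)
        assert plan.pairs() == [(0, 1, 1), (2, 3, 1)]

    def test_two_parents_forced(self):
        plan = solve_mating(
            GameteAllocation(np.array([6, 6]), 6), np.zeros((2, 2))
        )
        assert plan.pair_counts[0, 1] == 6

    def test_infeasible_degrees_rejected(self):
        with pytest.raises(ValueError):
            solve_mating(GameteAllocation(np.array([3, 1, 0]), 2), np.zeros((3, 3)))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_integer_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        n_off = int(rng.integers(2, 5))
        g = random_feasible_degrees(n, n_off, rng)
        cost = rng.normal(size=(n, n))
        cost = (cost + cost.T) / 2
        plan = solve_mating(GameteAllocation(g, n_off), cost)
        lp_cost = sum(cnt * cost[i, j] for i, j, cnt in plan.pairs())
        opt = enumerate_optimal_cost(g, cost)
        assert lp_cost == pytest.approx(opt, abs=1e-9)
        assert np.array_equal(plan.degrees, g)

    @pytest.mark.parametrize("seed", range(30))
    def test_degree_conservation_larger_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 15))
        n_off = int(rng.integers(5, 25))
        g = random_feasible_degrees(n, n_off, rng)
        cost = rng.normal(size=(n, n))
        plan = solve_mating(GameteAllocation(g, n_off), (cost + cost.T) / 2)
        assert np.array_equal(plan.degrees, g)


class TestRandomMating:
    def test_two_parents_forced(self):
        plan = random_mating(GameteAllocation(np.array([4, 4]), 4), 0)
        assert plan.pair_counts[0, 1] == 4

    @pytest.mark.parametrize("seed", range(20))
    def test_degrees_always_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        n_off = int(rng.integers(2, 15))
        g = random_feasible_degrees(n, n_off, rng)
        plan = random_mating(GameteAllocation(g, n_off), seed)
        assert np.array_equal(plan.degrees, g)
        assert np.all(np.diag(plan.pair_counts) == 0)

    def test_unique_plan_always_found(self):
        # g = (2,1,1): stuck states must be repaired to the unique plan
        for seed in range(200):
            plan = random_mating(GameteAllocation(np.array([2, 1, 1]), 2), seed)
            assert plan.pairs() == [(0, 1, 1), (0, 2, 1)]

    def test_lp_cost_no_worse_than_random(self):
        rng = np.random.default_rng(7)
        wins = []
        for seed in range(50):
            n, n_off = 8, 10
            g = random_feasible_degrees(n, n_off, rng)
            cost = rng.normal(size=(n, n))
            cost = (cost + cost.T) / 2
            lp = solve_mating(GameteAllocation(g, n_off), cost)
            rnd = random_mating(GameteAllocation(g, n_off), seed)
            cost_of = lambda p: sum(c * cost[i, j] for i, j, c in p.pairs())
            wins.append(cost_of(lp) <= cost_of(rnd) + 1e-9)
        assert all(wins)


class TestExpectedHomozygosity:
    def test_identical_full_homozygotes(self):
        L = 6
        G = np.full((2, 2), float(L))
        plan = MatePlan(np.array([[0, 3], [3, 0]]), 3)
        assert expected_progeny_homozygosity(G, plan, L) == pytest.approx(L)

    def test_opposite_full_homozygotes(self):
        G = np.array([[5.0, -5.0], [-5.0, 5.0]])
        plan = MatePlan(np.array([[0, 1], [1, 0]]), 1)
        assert expected_progeny_homozygosity(G, plan, 5) == pytest.approx(0.0)

    def test_micro_fixture_pair(self, micro_panel):
        # A x B: G_AB = 0, L = 4 -> per-locus (1, 0, 1/2, 1/2) sums to 2
        G = compute_grm(encode_genotypes(micro_panel))
        plan = MatePlan(
            np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]), 1
        )
        assert expected_progeny_homozygosity(G, plan, 4) == pytest.approx(2.0)
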