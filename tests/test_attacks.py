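import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp

from netattack import (
    Network,
    UsageError,
    complete,
    correlation_attack,
    fraction_to_count,
    path,
    sequential_attack,
    simultaneous_attack,
    star,
    threshold_attack,
)
from netattack.synthetic import erdrey, pref
from conftest import random_network


def small_graph(seed: int) -> Network:
    """Mixed ensemble of small connected graphs for equivalence checks."""
    if seed % 2 == 0:
        return erdrey(40, 120, seed=seed)
    return pref(40, 2, seed=seed)


class TestSimultaneous:
    def test_star_hub_first(self):
        for measure in ("tc", "sc", "degree"):
            res = simultaneous_attack(star(6), measure, 1)
            assert res.order == [0]
            assert res.evaluations == 1

    def test_order_is_descending_initial_ranking(self, rng):
        g = random_network(rng, 30, 0.2)
        from netattack import total_communicability

        c = total_communicability(g).values
        res = simultaneous_attack(g, "tc", 10)
        expected = np.argsort(-c, kind="stable")[:10].tolist()
        assert res.order == expected

    def test_complete_graph_index_tie_break(self):
        res = simultaneous_attack(complete(4), "tc", 4)
        assert res.order == [0, 1, 2, 3]

    def test_m_out_of_range(self):
        with pytest.raises(UsageError):
            simultaneous_attack(complete(4), "tc", 5)
        with pytest.raises(UsageError):
            simultaneous_attack(complete(4), "tc", 0)


class TestSequential:
    def test_first_removal_matches_simultaneous(self, rng):
        g = random_network(rng, 25, 0.2)
        assert (
            sequential_attack(g, "tc", 1).order
            == simultaneous_attack(g, "tc", 1).order
        )

    def test_evaluations_equal_m(self):
        g = erdrey(30, 90, seed=1)
        for m in (1, 5, 12):
            assert sequential_attack(g, "tc", m).evaluations == m

    def test_matches_brute_force_on_tree(self):
        """Full order on a 7-node tree vs a dense-exponential replay.

        The tree is asymmetric so TC values are well separated at every
        step (the only ties are isolated nodes at exactly 1, which both
        routes break identically by smallest id)."""
        g = Network(
            sp.coo_array(
                (
                    np.ones(6),
                    ([0, 0, 2, 3, 4, 4], [1, 5, 4, 4, 5, 6]),
                ),
                shape=(7, 7),
            )
        )
        res = sequential_attack(g, "tc", 7)
        # independent replay: dense expm, explicit row deletion
        a = g.adjacency.toarray()
        alive = list(range(7))
        expected = []
        while alive:
            sub = a[np.ix_(alive, alive)]
            tc = scipy.linalg.expm(sub).sum(axis=1)
            pick = alive[int(np.argmax(tc))]
            expected.append(pick)
            alive.remove(pick)
        assert res.order == expected

    def test_input_graph_not_mutated_by_default(self):
        g = complete(5)
        sequential_attack(g, "tc", 3)
        assert g.n_present == 5


class TestThreshold:
    @pytest.mark.parametrize("measure", ["tc", "degree"])
    def test_gamma_zero_reproduces_sequential(self, measure):
        for seed in range(6):
            g = small_graph(seed)
            m = 10
            seq = sequential_attack(g, measure, m)
            thr = threshold_attack(g, measure, m, gamma=0.0)
            assert thr.order == seq.order
            assert thr.evaluations == m

    def test_gamma_near_one_reproduces_simultaneous(self):
        for seed in range(4):
            g = small_graph(seed)
            sim = simultaneous_attack(g, "tc", 8)
            thr = threshold_attack(g, "tc", 8, gamma=0.999)
            assert thr.order == sim.order
            assert thr.evaluations == 1

    def test_cumulative_mass_respects_gamma_before_trigger(self):
        g = pref(60, 2, seed=5)
        gamma = 0.05
        res = threshold_attack(g, "tc", 30, gamma=gamma)
        window = 0.0
        for step in res.steps:
            if step.recomputed:
                window = 0.0
            # mass accumulated before this removal never exceeds gamma
            assert window <= gamma + 1e-12
            window = step.cumulative_mass
        assert 1 <= res.evaluations <= 30

    def test_gamma_out_of_range(self):
        g = complete(5)
        for gamma in (-0.1, 1.0, 1.5):
            with pytest.raises(UsageError):
                threshold_attack(g, "tc", 2, gamma=gamma)


class TestCorrelation:
    def test_disjoint_components_never_recompute(self):
        """Top two nodes in different components: the runner-up is never
        adjacent to the removed node, so the initial ranking is kept."""
        g = Network(sp.block_diag([star(5).adjacency, complete(3).adjacency]))
        res = correlation_attack(g, "tc", 2)
        assert res.order[0] == 0  # star hub
        assert res.steps[0].runner_up == 5  # a K3 node, other component
        assert res.evaluations == 1

    def test_star_runner_up_always_adjacent(self):
        res = correlation_attack(star(6), "tc", 2)
        assert res.order[0] == 0
        assert res.evaluations == 2

    def test_full_removal_handles_missing_runner_up(self):
        res = correlation_attack(path(3), "tc", 3)
        assert sorted(res.order) == [0, 1, 2]

    def test_remark_upper_bound_on_random_instances(self, rng):
        """Evaluations never exceed M + 1 - m*, with m* the first
        adjacent pair along the initial ranking's permuted superdiagonal."""
        from netattack import total_communicability

        checked = 0
        while checked < 100:
            g = random_network(rng, int(rng.integers(10, 31)), 0.15)
            m = int(rng.integers(2, g.n_present))
            c = total_communicability(g)
            perm = c.top(g.n_total, g.present_mask)
            a = g.adjacency
            m_star = None
            for i in range(1, m + 1):
                if i < g.n_total and a[perm[i - 1], perm[i]] > 0:
                    m_star = i
                    break
            res = correlation_attack(g, "tc", m)
            bound = m + 1 - m_star if m_star is not None else 1
            assert res.evaluations <= bound
            if m_star is not None and m_star <= m - 1:
                assert res.evaluations >= 2
            checked += 1

    def test_walk_order_two_sees_distance_two_runner_up(self):
        """On a path, hub and runner-up at distance 2 trigger only for l >= 2."""
        g = path(5)  # TC ranking: 2, then 1/3 tie -> 1 (distance 1) ...
        # build a graph where top two are at distance exactly 2:
        # two stars sharing no edge, joined through a middle node
        a = np.zeros((7, 7))
        for leaf in (2, 3):
            a[0, leaf] = a[leaf, 0] = 1
        for leaf in (4, 5):
            a[1, leaf] = a[leaf, 1] = 1
        a[0, 6] = a[6, 0] = 1
        a[1, 6] = a[6, 1] = 1
        g = Network(a)
        res1 = correlation_attack(g, "tc", 2, walk_order=1)
        res2 = correlation_attack(g, "tc", 2, walk_order=2)
        assert res1.steps[0].runner_up is not None
        assert res1.evaluations == 1  # top two not adjacent
        assert res2.evaluations == 2  # but joined by a length-2 walk

    def test_determinism(self):
        g = pref(50, 2, seed=9)
        a = correlation_attack(g, "tc", 10)
        b = correlation_attack(g, "tc", 10)
        assert a.order == b.order and a.evaluations == b.evaluations

    def test_walk_test_monotone_in_order(self, rng):
        """For a fixed matrix state, a longer walk budget can only turn
        the recompute test on, never off."""
        from netattack.attacks import _walk_connected

        for _ in range(20):
            g = random_network(rng, 15, 0.2)
            i, j = rng.choice(15, size=2, replace=False)
            hits = [
                _walk_connected(g.adjacency, int(i), int(j), l)
                for l in (1, 2, 3, 4)
            ]
            assert hits == sorted(hits)

    def test_first_recomputation_moves_earlier_with_order(self, rng):
        """Until the first recomputation all walk budgets share the same
        trajectory, so a longer budget can only trigger sooner.  (Counts
        over a whole attack are not comparable: an earlier recomputation
        changes the trajectory downstream.)"""

        def first_recompute(res):
            for step in res.steps[1:]:
                if step.recomputed:
                    return step.step
            return np.inf

        for seed in range(8):
            g = small_graph(seed)
            firsts = [
                first_recompute(correlation_attack(g, "tc", 15, walk_order=l))
                for l in (1, 2, 3)
            ]
            assert firsts[0] >= firsts[1] >= firsts[2]


class TestContracts:
    def test_order_nodes_distinct_and_were_present(self, rng):
        for strat, kwargs in [
            (simultaneous_attack, {}),
            (sequential_attack, {}),
            (threshold_attack, {"gamma": 0.05}),
            (correlation_attack, {}),
        ]:
            g = random_network(rng, 25, 0.2)
            res = strat(g, "tc", 12, **kwargs)
            assert len(set(res.order)) == 12
            assert all(0 <= i < 25 for i in res.order)

    def test_evaluation_ranges(self):
        g = erdrey(40, 120, seed=2)
        m = 15
        assert simultaneous_attack(g, "tc", m).evaluations == 1
        assert sequential_attack(g, "tc", m).evaluations == m
        for res in (
            threshold_attack(g, "tc", m, gamma=0.02),
            correlation_attack(g, "tc", m),
        ):
            assert 1 <= res.evaluations <= m

    def test_fraction_to_count_rounds_up(self):
        assert fraction_to_count(0.1, 2000) == 200
        assert fraction_to_count(0.001, 150) == 1
        assert fraction_to_count(1.0, 7) == 7
        with pytest.raises(UsageError):
            fraction_to_count(0.0, 10)
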