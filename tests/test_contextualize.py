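import numpy as np
import pytest

from diffgrn.boolnet import ACTIVATION, INHIBITION, find_attractor, \
    pattern_agreement
from diffgrn.contextualize import (GAParams, Individual, MasterMap,
                                   consensus, contextualize,
                                   cooperative_select, evaluate, mutate,
                                   rank_population, three_point_crossover)
from diffgrn.io_formats import InteractionRecord
from diffgrn.preprocess import PhenotypePattern
from diffgrn.synthetic import generate


def toy_master():
    recs = [InteractionRecord("A", "B", "activation"),
            InteractionRecord("B", "A", "unknown"),
            InteractionRecord("B", "C", "inhibition"),
            InteractionRecord("C", "A", "unknown")]
    return MasterMap(recs)


def make_ind(scalar):
    """Individual with a preset objective vector (o3 = 0)."""
    ind = Individual(np.ones(1, dtype=bool), np.ones(1, dtype=bool),
                     np.zeros(0, dtype=bool))
    ind.objectives = (scalar / 2, scalar / 2, 0.0)
    return ind


class TestCooperativeSelection:
    def test_reference_trace(self):
        """Scalars [1,5,9,12]: pick best, overwrite to (5+9)/2, pick 5."""
        pop = [make_ind(s) for s in (1, 5, 9, 12)]
        working = [ind.scalar for ind in pop]
        first, second = cooperative_select(pop, working)
        assert first is pop[0]
        assert second is pop[1]
        assert working[0] == 7.0

    def test_all_equal_fitness_deterministic_tiebreak(self):
        pop = [make_ind(4) for _ in range(4)]
        first, second = cooperative_select(pop, [4.0] * 4)
        assert first is pop[0]
        assert second is pop[1]

    def test_never_returns_same_individual_twice(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scalars = rng.integers(0, 10, size=6).tolist()
            pop = [make_ind(s) for s in scalars]
            a, b = cooperative_select(pop, [float(s) for s in scalars])
            assert a is not b

    def test_small_population_degrades_gracefully(self):
        pop = [make_ind(1), make_ind(2)]
        a, b = cooperative_select(pop, [1.0, 2.0])
        assert {id(a), id(b)} == {id(pop[0]), id(pop[1])}


class TestMutation:
    def _ind(self, n=100, u=100):
        return Individual(np.zeros(n, dtype=bool), np.ones(n, dtype=bool),
                          np.zeros(u, dtype=bool))

    def test_rate_zero_tail_is_identity(self):
        # rate must be in (0,1); a tiny rate leaves bits mostly unchanged
        rng = np.random.default_rng(1)
        out = mutate(self._ind(), 1e-12, rng)
        assert not out.bits1.any() and out.bits2.all()

    def test_high_rate_flips_almost_everything(self):
        rng = np.random.default_rng(2)
        out = mutate(self._ind(), 1 - 1e-12, rng)
        assert out.bits1.all() and not out.bits2.any() \
            and out.signbits.all()

    def test_flip_rate_matches_binomial_model(self):
        """Empirical flips per 100-bit subarray at rate 0.01 stay within
        3 sigma of the Binomial(100, 0.01) mean over 10^4 trials."""
        rng = np.random.default_rng(3)
        rate, n_trials, n_bits = 0.01, 10_000, 100
        base = self._ind(n_bits, n_bits)
        flips = np.zeros(3)
        for _ in range(n_trials):
            out = mutate(base, rate, rng)
            flips += [out.bits1.sum(), (~out.bits2).sum(),
                      out.signbits.sum()]
        mean = flips / n_trials
        sigma = np.sqrt(n_bits * rate * (1 - rate) / n_trials)
        assert np.all(np.abs(mean - n_bits * rate) < 3 * sigma)

    def test_original_untouched(self):
        rng = np.random.default_rng(4)
        base = self._ind()
        mutate(base, 0.5, rng)
        assert not base.bits1.any()


class TestCrossover:
    def _pair(self, n=40, u=10):
        rng = np.random.default_rng(7)
        p1 = Individual(np.zeros(n, bool), np.zeros(n, bool),
                        np.zeros(u, bool))
        p2 = Individual(np.ones(n, bool), np.ones(n, bool),
                        np.ones(u, bool))
        return p1, p2, rng

    def test_prob_zero_returns_copies(self):
        p1, p2, rng = self._pair()
        c1, c2 = three_point_crossover(p1, p2, 0.0, rng)
        assert not c1.bits1.any() and c2.bits1.all()

    def test_identical_parents_unchanged(self):
        rng = np.random.default_rng(8)
        p = Individual(rng.random(30) < 0.5, rng.random(30) < 0.5,
                       rng.random(5) < 0.5)
        c1, c2 = three_point_crossover(p, p.copy(), 1.0, rng)
        for c in (c1, c2):
            assert np.array_equal(c.bits1, p.bits1)
            assert np.array_equal(c.bits2, p.bits2)
            assert np.array_equal(c.signbits, p.signbits)

    def test_prefix_suffix_structure_per_subarray(self):
        """child1 = p1-prefix + p2-suffix independently in each subarray."""
        p1, p2, rng = self._pair()
        for _ in range(20):
            c1, c2 = three_point_crossover(p1, p2, 1.0, rng)
            for name in ("bits1", "bits2", "signbits"):
                a, b = getattr(c1, name), getattr(c2, name)
                # all-zero prefix then all-one suffix (and the complement)
                cut = int(np.argmax(a)) if a.any() else a.size
                assert not a[:cut].any() and a[cut:].all()
                assert b[:cut].all() and not b[cut:].any()
                assert 1 <= cut <= a.size - 1 or a.size < 2

    def test_parents_not_modified(self):
        p1, p2, rng = self._pair()
        three_point_crossover(p1, p2, 1.0, rng)
        assert not p1.bits1.any() and p2.bits1.all()


class TestEvaluate:
    def test_all_absent_gives_all_on_attractor(self):
        master = toy_master()
        patA = PhenotypePattern("A", {"A": True, "B": False, "C": True})
        patB = PhenotypePattern("B", {"A": True, "B": True, "C": True})
        ind = Individual(np.zeros(4, bool), np.zeros(4, bool),
                         np.zeros(2, bool))
        o1, o2, o3 = evaluate(ind, master, patA, patB)
        # empty networks: every gene unregulated -> all ON fixed point
        assert o1 == 1.0  # one OFF gene in pattern A
        assert o2 == 0.0
        assert o3 == 8.0  # 4 pruned edges in each network

    def test_signbit_locality(self):
        """Flipping a sign bit changes o1/o2 only if the edge is present."""
        master = toy_master()
        patA = PhenotypePattern("A", {"A": True, "B": True, "C": False})
        patB = PhenotypePattern("B", {"A": False, "B": True, "C": True})
        rng = np.random.default_rng(9)
        for _ in range(20):
            bits1 = rng.random(4) < 0.7
            bits2 = rng.random(4) < 0.7
            sb = rng.random(2) < 0.5
            base = evaluate(Individual(bits1.copy(), bits2.copy(), sb.copy()),
                            master, patA, patB)
            for j, edge_idx in enumerate(master.unknown_idx):
                flipped = sb.copy()
                flipped[j] = ~flipped[j]
                new = evaluate(Individual(bits1.copy(), bits2.copy(),
                                          flipped), master, patA, patB)
                if not bits1[edge_idx] and not bits2[edge_idx]:
                    assert new == base

    def test_sign_sharing_between_decoded_networks(self):
        master = toy_master()
        rng = np.random.default_rng(10)
        for _ in range(10):
            ind = Individual(np.ones(4, bool), rng.random(4) < 0.5,
                             rng.random(2) < 0.5)
            net1, net2 = master.decode(ind)
            signs1 = {(e.source, e.target): e.sign for e in net1.edges}
            signs2 = {(e.source, e.target): e.sign for e in net2.edges}
            for key in set(signs1) & set(signs2):
                assert signs1[key] == signs2[key]


class TestConsensus:
    def test_single_solution_is_identity(self):
        master = toy_master()
        patA = PhenotypePattern("A", {"A": True, "B": False, "C": True})
        patB = PhenotypePattern("B", {"A": True, "B": True, "C": True})
        ind = Individual(np.array([1, 0, 1, 1], bool),
                         np.array([1, 1, 0, 1], bool),
                         np.array([1, 0], bool))
        evaluate(ind, master, patA, patB)
        net1, net2, signs = consensus([ind], master)
        assert {(e.source, e.target) for e in net1.edges} == \
            {("A", "B"), ("B", "C"), ("C", "A")}
        assert {(e.source, e.target) for e in net2.edges} == \
            {("A", "B"), ("B", "A"), ("C", "A")}
        assert signs == {("B", "A"): ACTIVATION, ("C", "A"): INHIBITION}

    def test_majority_threshold(self):
        master = toy_master()
        patA = PhenotypePattern("A", {"A": True, "B": False, "C": True})
        patB = PhenotypePattern("B", {"A": True, "B": True, "C": True})
        inds = []
        for k in range(5):
            present = k < 3  # edge 0 present in 3/5 solutions
            ind = Individual(
                np.array([present, 1, 1, 1], bool),
                np.array([1, 1, 1, 1], bool), np.ones(2, bool))
            evaluate(ind, master, patA, patB)
            ind.objectives = (0.0, 0.0, 0.0)  # equal rank: all vote
            inds.append(ind)
        net1, _, _ = consensus(inds, master, consensus_fraction=1.0,
                               consensus_threshold=0.5)
        assert ("A", "B", "activation") in net1.edge_set()


@pytest.fixture(scope="module")
def instance():
    return generate(seed=1)


@pytest.fixture(scope="module")
def result(instance):
    master = MasterMap(instance.master, genes=instance.genes)
    params = GAParams(population_size=60, generations=40, seed=5)
    return contextualize(master, instance.patternA, instance.patternB,
                         params)


class TestContextualize:
    def test_reaches_perfect_agreement(self, instance, result):
        for net, pat in ((result.net1, instance.patternA),
                         (result.net2, instance.patternB)):
            init = net.state_from_pattern(pat.states)
            att = find_attractor(net, init)
            assert pattern_agreement(att, init) == 0.0
            assert att.is_fixed_point

    def test_elitism_best_scalar_nonincreasing(self, result):
        sums = [o[0] + o[1] for o in result.history]
        assert all(b <= a for a, b in zip(sums, sums[1:]))

    def test_deterministic_under_fixed_seed(self, instance, result):
        master = MasterMap(instance.master, genes=instance.genes)
        params = GAParams(population_size=60, generations=40, seed=5)
        again = contextualize(master, instance.patternA, instance.patternB,
                              params)
        assert again.net1.edge_set() == result.net1.edge_set()
        assert again.net2.edge_set() == result.net2.edge_set()
        assert again.consensus_signs == result.consensus_signs

    def test_consensus_signs_cover_all_unknown_edges(self, instance, result):
        assert set(result.consensus_signs) == set(instance.true_signs)

    def test_no_unknown_signs_degenerate_encoding(self):
        recs = [InteractionRecord("A", "B", "activation"),
                InteractionRecord("B", "A", "activation")]
        master = MasterMap(recs)
        pat = PhenotypePattern("A", {"A": True, "B": True})
        res = contextualize(master, pat,
                            PhenotypePattern("B", pat.states.copy()),
                            GAParams(population_size=10, generations=5,
                                     seed=0))
        assert res.consensus_signs == {}
        assert res.best_objectives[0] == 0.0

    def test_parsimony_objective_counts_pruned_edges(self):
        master = toy_master()
        patA = PhenotypePattern("A", {"A": True, "B": True, "C": False})
        patB = PhenotypePattern("B", {"A": True, "B": True, "C": False})
        full = Individual(np.ones(4, bool), np.ones(4, bool),
                          np.ones(2, bool))
        assert evaluate(full, master, patA, patB)[2] == 0.0
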