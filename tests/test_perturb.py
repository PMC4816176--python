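import itertools
import math

import numpy as np
import pytest

from conftest import random_signed_network
from oracle_utils import tabulated_attractor

from diffgrn.boolnet import ACTIVATION, INHIBITION, SignedNetwork
from diffgrn.circuits import CandidateSet
from diffgrn.perturb import (ScanConfig, reversion_clamp, scan_multitarget,
                             simulate_perturbation, single_gene_weights,
                             read_scan, write_scan)
from diffgrn.preprocess import PhenotypePattern


def cascade(n=10):
    """Linear activation cascade g0 -> g1 -> ... -> g(n-1)."""
    genes = [f"g{i}" for i in range(n)]
    edges = [(genes[i], genes[i + 1], ACTIVATION) for i in range(n - 1)]
    return SignedNetwork(genes, edges)


def pattern(net, mapping, pheno="P"):
    return PhenotypePattern(pheno, {g: bool(mapping[g]) for g in net.genes})


class TestSimulatePerturbation:
    def test_empty_clamp_on_fixed_point_is_zero(self):
        net = SignedNetwork(["A", "B"],
                            [("A", "B", ACTIVATION), ("B", "A", ACTIVATION)])
        init = pattern(net, {"A": 1, "B": 1})
        res = simulate_perturbation(net, {}, init)
        assert res.gec == 0 and res.changed_fraction == 0.0

    def test_pure_clamp_scores_zero(self):
        """Clamping k genes with no downstream effect: changed = k, gec = 0."""
        net = SignedNetwork(["A", "B", "C"], [])  # all unregulated -> ON
        init = pattern(net, {"A": 1, "B": 1, "C": 1})
        res = simulate_perturbation(net, {"A": False, "B": False}, init)
        assert res.gec == 0
        assert res.changed_fraction == pytest.approx(2 / 3)

    def test_root_clamp_flips_cascade(self):
        """Clamping the cascade root OFF turns every descendant OFF."""
        net = cascade(10)
        init = pattern(net, {g: 1 for g in net.genes})  # all-ON fixed point
        res = simulate_perturbation(net, {"g0": False}, init)
        assert res.gec == 10 - 1
        assert res.changed_fraction == 1.0

    def test_matches_clamped_transition_tabulation(self):
        """Clamped dynamics equal the brute-force transition-graph oracle."""
        rng = np.random.default_rng(41)
        for _ in range(20):
            net = random_signed_network(rng, 8)
            init = {g: bool(rng.random() < 0.5) for g in net.genes}
            k = int(rng.integers(1, 4))
            clamp_genes = rng.choice(net.genes, size=k, replace=False)
            clamp = {g: bool(rng.random() < 0.5) for g in clamp_genes}
            res = simulate_perturbation(net, clamp, pattern(net, init))
            cyc = tabulated_attractor(net, init, clamp)
            occ = {g: np.mean([s[g] for s in cyc]) for g in net.genes}
            changed = sum(
                1 for g in net.genes
                if (occ[g] > 0.5 and not init[g])
                or (occ[g] < 0.5 and init[g]))
            assert res.gec == changed - k
            assert res.changed_fraction == pytest.approx(changed / 8)

    def test_gec_bounded_by_free_genes(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            net = random_signed_network(rng, 7)
            init = {g: bool(rng.random() < 0.5) for g in net.genes}
            clamp = {g: not init[g] for g in net.genes[:3]}
            res = simulate_perturbation(net, clamp, pattern(net, init))
            assert res.gec <= net.n_genes - len(clamp)

    def test_unknown_clamp_gene_rejected(self):
        net = cascade(3)
        with pytest.raises(KeyError):
            simulate_perturbation(net, {"nope": True},
                                  pattern(net, {g: 1 for g in net.genes}))


class TestScan:
    def _setup(self):
        net = cascade(6)
        init = pattern(net, {g: 1 for g in net.genes}, "B")
        ref = pattern(net, {g: 0 for g in net.genes}, "A")
        return net, init, ref

    def test_exhaustive_combination_count(self):
        net, init, ref = self._setup()
        cands = CandidateSet(["g0", "g1", "g2"], [])
        res = scan_multitarget(net, cands, init, ref,
                               ScanConfig(max_size=2, max_per_size=10 ** 6))
        assert len(res) == math.comb(3, 1) + math.comb(3, 2)

    def test_solo_genes_only_size_one(self):
        net, init, ref = self._setup()
        cands = CandidateSet(["g0", "g1"], ["g5"])
        res = scan_multitarget(net, cands, init, ref,
                               ScanConfig(max_size=3))
        for r in res:
            if "g5" in r.combination:
                assert r.size == 1

    def test_no_duplicate_combinations(self):
        net, init, ref = self._setup()
        cands = CandidateSet(["g0", "g1", "g2", "g3"], ["g4"])
        res = scan_multitarget(net, cands, init, ref,
                               ScanConfig(max_size=3, max_per_size=3,
                                          seed=11))
        combos = [r.combination for r in res]
        assert len(combos) == len(set(combos))

    def test_sampling_cap_respected_and_exhaustive_when_loose(self):
        net, init, ref = self._setup()
        cands = CandidateSet(["g0", "g1", "g2", "g3", "g4"], [])
        capped = scan_multitarget(net, cands, init, ref,
                                  ScanConfig(max_size=3, max_per_size=4,
                                             seed=1))
        sizes = {}
        for r in capped:
            sizes[r.size] = sizes.get(r.size, 0) + 1
        assert sizes[2] == 4 and sizes[3] == 4
        loose_a = scan_multitarget(net, cands, init, ref,
                                   ScanConfig(max_size=3, seed=1))
        loose_b = scan_multitarget(net, cands, init, ref,
                                   ScanConfig(max_size=3, seed=99))
        assert [r.combination for r in loose_a] == \
            [r.combination for r in loose_b]

    def test_top_matches_exhaustive_search(self):
        """Best gec in the scan equals the best over all subsets <= 3,
        recomputed combination by combination."""
        rng = np.random.default_rng(47)
        net = random_signed_network(rng, 12, density=0.2)
        init_map = {g: bool(rng.random() < 0.5) for g in net.genes}
        ref_map = {g: not init_map[g] for g in net.genes}
        init = pattern(net, init_map, "B")
        ref = pattern(net, ref_map, "A")
        cands = CandidateSet(sorted(net.genes)[:8], [])
        res = scan_multitarget(net, cands, init, ref,
                               ScanConfig(max_size=3))
        best = max(
            simulate_perturbation(net, reversion_clamp(c, ref), init).gec
            for k in (1, 2, 3)
            for c in itertools.combinations(cands.circuit_genes, k))
        assert res[0].gec == best

    def test_ranking_order(self):
        net, init, ref = self._setup()
        cands = CandidateSet(["g0", "g1", "g2"], [])
        res = scan_multitarget(net, cands, init, ref, ScanConfig(max_size=2))
        keys = [(-r.gec, r.size, r.combination) for r in res]
        assert keys == sorted(keys)

    def test_round_trip(self, tmp_path):
        net, init, ref = self._setup()
        cands = CandidateSet(["g0", "g1"], [])
        res = scan_multitarget(net, cands, init, ref, ScanConfig(max_size=2))
        p = tmp_path / "combos.tsv"
        write_scan(res, p)
        assert read_scan(p) == res


class TestWeights:
    def test_rescaling_endpoints(self):
        net = cascade(6)
        init = pattern(net, {g: 1 for g in net.genes}, "B")
        ref = pattern(net, {g: 0 for g in net.genes}, "A")
        cands = CandidateSet(["g0", "g5"], [])  # root vs leaf
        res = scan_multitarget(net, cands, init, ref, ScanConfig(max_size=1))
        w = single_gene_weights(res, cands)
        assert w["g0"] == 1.0  # flips everything downstream
        assert w["g5"] == 0.0  # inert leaf

    def test_all_equal_gec_gives_all_ones(self):
        net = SignedNetwork(["A", "B"], [])
        init = pattern(net, {"A": 1, "B": 1}, "B")
        ref = pattern(net, {"A": 0, "B": 0}, "A")
        cands = CandidateSet(["A", "B"], [])
        res = scan_multitarget(net, cands, init, ref, ScanConfig(max_size=1))
        w = single_gene_weights(res, cands)
        assert w == {"A": 1.0, "B": 1.0}

    def test_monotone_in_single_gene_gec(self):
        rng = np.random.default_rng(53)
        for _ in range(10):
            net = random_signed_network(rng, 9, density=0.25)
            init_map = {g: bool(rng.random() < 0.5) for g in net.genes}
            init = pattern(net, init_map, "B")
            ref = pattern(net, {g: not v for g, v in init_map.items()}, "A")
            cands = CandidateSet(sorted(net.genes)[:5], [])
            res = scan_multitarget(net, cands, init, ref,
                                   ScanConfig(max_size=1))
            w = single_gene_weights(res, cands)
            gecs = {r.combination[0]: r.gec for r in res}
            for a in cands.circuit_genes:
                for b in cands.circuit_genes:
                    if gecs[a] < gecs[b]:
                        assert w[a] < w[b]

    def test_missing_single_result_is_internal_error(self):
        cands = CandidateSet(["A"], [])
        with pytest.raises(RuntimeError):
            single_gene_weights([], cands)
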