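"""Contextualization of a literature interaction map by a multiobjective GA.

A curated interaction map aggregates edges observed across many cell types,
so its Boolean attractors need not match any one phenotype.  The genetic
algorithm prunes the map into *two* phenotype-specific networks at once and
resolves unknown interaction signs shared by both.

Genome encoding (three bit subarrays over one master edge list):

* ``bits1`` — presence of each candidate edge in network 1;
* ``bits2`` — presence of each candidate edge in network 2;
* ``signbits`` — one bit per originally-unknown edge (1 = activation,
  0 = inhibition), applied identically to both networks.

Objectives, all minimized:

* ``o1`` — mismatch of network 1's attractor (reached from phenotype A's
  binarized pattern) against that pattern, plus (cycle length − 1) as an
  instability penalty;
* ``o2`` — the same for network 2 / phenotype B;
* ``o3`` — total number of pruned edges over both networks (parsimony: the
  map is trusted unless the data demand otherwise).

The evolutionary loop is NSGA-II-style (elitist survival by nondominated
sorting and crowding distance), but parent mating uses *cooperative
selection* on a scalarized rank: the best individual is picked, its working
fitness is overwritten with the mean of the second and third best, so the
next pick necessarily selects a different individual.  Variation is a
three-point crossover — one independent cut per subarray — and independent
per-bit mutation at a fixed rate per subarray.

Because final populations retain variability, the output is a *consensus*
pair of networks over the top-ranking solutions: an edge enters consensus
network k iff present in more than a threshold fraction of them, and each
unknown-sign edge takes its majority sign.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boolnet import (ACTIVATION, INHIBITION, SignedNetwork, find_attractor,
                      pattern_agreement)
from .io_formats import UNKNOWN, InteractionRecord
from .preprocess import PhenotypePattern

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAParams:
    """Tuning knobs of the contextualization GA.

    Defaults follow the reference configuration: population 700,
    250 generations, per-bit mutation 0.01 within each subarray, crossover
    probability 0.9.  ``consensus_fraction`` is the share of top-ranking
    solutions entering the consensus; ``consensus_threshold`` the majority
    fraction an edge must exceed to be kept.
    """

    population_size: int = 700
    generations: int = 250
    mutation_rate: float = 0.01
    crossover_prob: float = 0.9
    seed: int = 0
    consensus_fraction: float = 0.1
    consensus_threshold: float = 0.5
    max_steps: int | None = None  # attractor step budget per evaluation

    def __post_init__(self) -> None:
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must lie in [0, 1]")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")


@dataclass
class Individual:
    """One GA genome: two presence subarrays and a shared sign subarray."""

    bits1: np.ndarray
    bits2: np.ndarray
    signbits: np.ndarray
    objectives: tuple[float, float, float] | None = None

    def copy(self) -> "Individual":
        return Individual(self.bits1.copy(), self.bits2.copy(),
                          self.signbits.copy(), None)

    @property
    def scalar(self) -> float:
        """Agreement scalarization o1 + o2 used for ranking and consensus."""
        return self.objectives[0] + self.objectives[1]


class MasterMap:
    """The master edge list the genome subarrays index.

    Splits edges into known-sign and unknown-sign; unknown edges map to
    positions in the sign subarray in master order.
    """

    def __init__(self, records: Sequence[InteractionRecord],
                 genes: Sequence[str] | None = None) -> None:
        if not records:
            raise ValueError("master interaction map is empty")
        self.records = list(records)
        if genes is None:
            seen: list[str] = []
            for r in self.records:
                for g in (r.source, r.target):
                    if g not in seen:
                        seen.append(g)
            genes = seen
        self.genes = list(genes)
        self.unknown_idx = [i for i, r in enumerate(self.records)
                            if r.sign == UNKNOWN]
        self._unknown_pos = {e: j for j, e in enumerate(self.unknown_idx)}
        self._index_arrays()

    @property
    def n_edges(self) -> int:
        return len(self.records)

    @property
    def n_unknown(self) -> int:
        return len(self.unknown_idx)

    def _index_arrays(self) -> None:
        """Precompute integer edge indexing for fast genome evaluation."""
        gi = {g: i for i, g in enumerate(self.genes)}
        self._src = np.array([gi[r.source] for r in self.records])
        self._tgt = np.array([gi[r.target] for r in self.records])
        # +1 activation, -1 inhibition, 0 unknown (resolved by signbits)
        code = {ACTIVATION: 1, INHIBITION: -1, UNKNOWN: 0}
        self._sign_code = np.array([code[r.sign] for r in self.records])
        self._unknown_mask = self._sign_code == 0

    def resolve_signs(self, signbits: np.ndarray) -> list[str]:
        """Per-edge signs with unknowns resolved by the sign subarray."""
        signs = []
        for i, r in enumerate(self.records):
            if r.sign == UNKNOWN:
                signs.append(ACTIVATION if signbits[self._unknown_pos[i]]
                             else INHIBITION)
            else:
                signs.append(r.sign)
        return signs

    def decode(self, ind: Individual) -> tuple[SignedNetwork, SignedNetwork]:
        """Materialize the two phenotype-specific networks of a genome."""
        signs = self.resolve_signs(ind.signbits)
        nets = []
        for bits in (ind.bits1, ind.bits2):
            edges = [(r.source, r.target, signs[i])
                     for i, r in enumerate(self.records) if bits[i]]
            nets.append(SignedNetwork(self.genes, edges))
        return nets[0], nets[1]


class _FastNet:
    """Minimal majority-rule network decoded straight into count matrices.

    Duck-typed stand-in for :class:`SignedNetwork` inside
    :func:`find_attractor`; skips gene/edge object construction, which
    dominates GA runtime otherwise.
    """

    __slots__ = ("n_genes", "_act_i", "_inh_i", "unregulated")

    def __init__(self, master: MasterMap, bits: np.ndarray,
                 signs: np.ndarray) -> None:
        n = len(master.genes)
        present = np.flatnonzero(bits)
        src = master._src[present]
        tgt = master._tgt[present]
        s = signs[present]
        # master edges are unique (source, target) pairs, so plain
        # assignment accumulates correctly
        self._act_i = np.zeros((n, n), dtype=np.int16)
        self._inh_i = np.zeros((n, n), dtype=np.int16)
        self._act_i[tgt[s > 0], src[s > 0]] = 1
        self._inh_i[tgt[s < 0], src[s < 0]] = 1
        regulated = np.zeros(n, dtype=bool)
        regulated[tgt] = True
        self.unregulated = ~regulated
        self.n_genes = n


def evaluate(ind: Individual, master: MasterMap,
             patternA: PhenotypePattern, patternB: PhenotypePattern,
             max_steps: int | None = None) -> tuple[float, float, float]:
    """Objective vector (o1, o2, o3) of one genome; caches on the genome."""
    signs = master._sign_code.copy()
    if master.n_unknown:
        signs[master._unknown_mask] = np.where(ind.signbits, 1, -1)
    objs = []
    for bits, pat in ((ind.bits1, patternA), (ind.bits2, patternB)):
        net = _FastNet(master, bits, signs)
        init = np.array([pat.states[g] for g in master.genes], dtype=bool)
        att = find_attractor(net, init, max_steps=max_steps)
        objs.append(pattern_agreement(att, init) + (len(att) - 1))
    o3 = float((master.n_edges - int(ind.bits1.sum()))
               + (master.n_edges - int(ind.bits2.sum())))
    ind.objectives = (objs[0], objs[1], o3)
    return ind.objectives


def cooperative_select(population: list[Individual],
                       working: list[float] | None = None,
                       fronts_of: list[int] | None = None
                       ) -> tuple[Individual, Individual]:
    """Pick two distinct parents by cooperative selection.

    Ranking is by (nondominated front, working scalar fitness), ties broken
    by index.  After the first pick, the winner's *working* fitness is
    overwritten with the mean of the second- and third-best working values,
    which forces the second pick onto a different individual.  Stored
    objective vectors are never touched.
    """
    n = len(population)
    if working is None:
        working = [ind.scalar for ind in population]
    if fronts_of is None:
        fronts_of = [0] * n
    if n < 3:
        log.warning("population < 3: falling back to plain best-two")
        order = sorted(range(n), key=lambda i: (fronts_of[i], working[i], i))
        return population[order[0]], population[order[-1] if n > 1 else 0]

    def ranked() -> list[int]:
        return sorted(range(n), key=lambda i: (fronts_of[i], working[i], i))

    order = ranked()
    first = order[0]
    working[first] = 0.5 * (working[order[1]] + working[order[2]])
    second = ranked()[0]
    if second == first:  # only possible when the averaged value still wins
        second = ranked()[1]
    return population[first], population[second]


def mutate(ind: Individual, rate: float,
           rng: np.random.Generator) -> Individual:
    """Independent per-bit flips at probability ``rate`` in each subarray."""
    out = ind.copy()
    for arr in (out.bits1, out.bits2, out.signbits):
        if arr.size:
            flips = rng.random(arr.size) < rate
            arr ^= flips
    return out


def three_point_crossover(p1: Individual, p2: Individual, prob: float,
                          rng: np.random.Generator
                          ) -> tuple[Individual, Individual]:
    """Recombine parents with one independent cut point per subarray.

    With probability ``1 - prob`` the parents are returned unchanged
    (copies).  Otherwise, within every subarray child 1 takes parent 1's
    prefix and parent 2's suffix, child 2 the complement, so the two
    network subarrays and the sign subarray recombine independently.
    """
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() >= prob:
        return c1, c2
    for name in ("bits1", "bits2", "signbits"):
        a = getattr(c1, name)
        b = getattr(c2, name)
        if a.size < 2:
            continue
        cut = int(rng.integers(1, a.size))
        a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
    return c1, c2


def fast_nondominated_fronts(objectives: list[tuple[float, ...]]
                             ) -> list[list[int]]:
    """NSGA-II nondominated sorting; returns fronts as index lists.

    The pairwise domination matrix is computed with one numpy broadcast
    (x dominates y iff x <= y componentwise with at least one strict <).
    """
    obj = np.asarray(objectives, dtype=float)
    n = len(obj)
    le = (obj[:, None, :] <= obj[None, :, :]).all(axis=2)
    lt = (obj[:, None, :] < obj[None, :, :]).any(axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    dominated_by = dom.sum(axis=0)
    fronts: list[list[int]] = []
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.flatnonzero((dominated_by == 0) & ~assigned)
        fronts.append(current.tolist())
        assigned[current] = True
        dominated_by = dominated_by - dom[current].sum(axis=0)
    return fronts


def _dom(a: tuple[float, ...], b: tuple[float, ...]) -> bool:
    return all(x <= y for x, y in zip(a, b)) and any(
        x < y for x, y in zip(a, b))


def crowding_distance(objectives: list[tuple[float, ...]],
                      front: list[int]) -> dict[int, float]:
    dist = {i: 0.0 for i in front}
    if len(front) <= 2:
        return {i: math.inf for i in front}
    n_obj = len(objectives[front[0]])
    for m in range(n_obj):
        order = sorted(front, key=lambda i: objectives[i][m])
        lo = objectives[order[0]][m]
        hi = objectives[order[-1]][m]
        dist[order[0]] = dist[order[-1]] = math.inf
        if hi == lo:
            continue
        for k in range(1, len(order) - 1):
            gap = objectives[order[k + 1]][m] - objectives[order[k - 1]][m]
            dist[order[k]] += gap / (hi - lo)
    return dist


def rank_population(population: list[Individual]
                    ) -> tuple[list[int], list[list[int]]]:
    """front index per individual + the fronts themselves."""
    objs = [ind.objectives for ind in population]
    fronts = fast_nondominated_fronts(objs)
    fronts_of = [0] * len(population)
    for k, front in enumerate(fronts):
        for i in front:
            fronts_of[i] = k
    return fronts_of, fronts


def _survival(population: list[Individual], size: int) -> list[Individual]:
    """NSGA-II elitist truncation to ``size`` individuals."""
    objs = [ind.objectives for ind in population]
    fronts = fast_nondominated_fronts(objs)
    survivors: list[int] = []
    for front in fronts:
        if len(survivors) + len(front) <= size:
            survivors.extend(front)
        else:
            dist = crowding_distance(objs, front)
            # keep the best agreement scalar first so elitism on o1+o2 holds
            rest = sorted(front,
                          key=lambda i: (-dist[i],
                                         population[i].scalar, i))
            best_scalar = min(front, key=lambda i: (population[i].scalar, i))
            if best_scalar in rest[size - len(survivors):]:
                rest.remove(best_scalar)
                rest.insert(0, best_scalar)
            survivors.extend(rest[:size - len(survivors)])
            break
    return [population[i] for i in survivors]


def initial_population(master: MasterMap, params: GAParams,
                       rng: np.random.Generator) -> list[Individual]:
    """Seed population: a few all-present genomes plus 50 %-presence noise.

    Starting from the full map reflects trust in the literature edges; the
    random half-dense genomes supply diversity.
    """
    e, u = master.n_edges, master.n_unknown
    pop: list[Individual] = []
    n_full = max(1, params.population_size // 10)
    for _ in range(n_full):
        pop.append(Individual(np.ones(e, dtype=bool), np.ones(e, dtype=bool),
                              rng.random(u) < 0.5))
    while len(pop) < params.population_size:
        pop.append(Individual(rng.random(e) < 0.5, rng.random(e) < 0.5,
                              rng.random(u) < 0.5))
    return pop


@dataclass
class ContextualizationResult:
    net1: SignedNetwork
    net2: SignedNetwork
    consensus_signs: dict[tuple[str, str], str]
    population: list[Individual]
    history: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def best_objectives(self) -> tuple[float, float, float]:
        return min((ind.objectives for ind in self.population),
                   key=lambda o: (o[0] + o[1], o[2]))


def contextualize(master: MasterMap | Sequence[InteractionRecord],
                  patternA: PhenotypePattern, patternB: PhenotypePattern,
                  params: GAParams = GAParams()) -> ContextualizationResult:
    """Run the full GA and return consensus networks + final population."""
    if not isinstance(master, MasterMap):
        master = MasterMap(master)
    missing = set(master.genes) - set(patternA.states) | \
        (set(master.genes) - set(patternB.states))
    if missing:
        raise ValueError(f"patterns missing genes: {sorted(missing)}")
    rng = np.random.default_rng(params.seed)
    pop = initial_population(master, params, rng)
    for ind in pop:
        evaluate(ind, master, patternA, patternB, params.max_steps)
    history: list[tuple[float, float, float]] = []
    for gen in range(params.generations):
        fronts_of, _ = rank_population(pop)
        working = [ind.scalar for ind in pop]
        offspring: list[Individual] = []
        while len(offspring) < params.population_size:
            pa, pb = cooperative_select(pop, working, fronts_of)
            c1, c2 = three_point_crossover(pa, pb, params.crossover_prob, rng)
            c1 = mutate(c1, params.mutation_rate, rng)
            c2 = mutate(c2, params.mutation_rate, rng)
            offspring.extend([c1, c2])
        offspring = offspring[:params.population_size]
        for ind in offspring:
            evaluate(ind, master, patternA, patternB, params.max_steps)
        pop = _survival(pop + offspring, params.population_size)
        best = min((ind.objectives for ind in pop),
                   key=lambda o: (o[0] + o[1], o[2]))
        history.append(best)
        log.debug("generation %d: best objectives %s", gen, best)
    net1, net2, signs = consensus(pop, master, params.consensus_fraction,
                                  params.consensus_threshold)
    return ContextualizationResult(net1=net1, net2=net2,
                                   consensus_signs=signs,
                                   population=pop, history=history)


def consensus(solutions: list[Individual], master: MasterMap,
              consensus_fraction: float = 0.1,
              consensus_threshold: float = 0.5
              ) -> tuple[SignedNetwork, SignedNetwork,
                         dict[tuple[str, str], str]]:
    """Majority-vote consensus over the top-ranking solutions.

    Solutions are ranked by (nondominated front, o1+o2); the top
    ``consensus_fraction`` share (at least one) vote.  An edge enters
    consensus network k iff present in strictly more than
    ``consensus_threshold`` of the voters; each originally-unknown edge
    takes its majority sign (tie -> activation, logged).  The two networks
    are treated independently.
    """
    if not solutions:
        raise ValueError("no solutions to build a consensus from")
    fronts_of, _ = rank_population(solutions)
    order = sorted(range(len(solutions)),
                   key=lambda i: (fronts_of[i], solutions[i].scalar, i))
    k = max(1, math.ceil(consensus_fraction * len(solutions)))
    top = [solutions[i] for i in order[:k]]
    votes1 = np.mean([ind.bits1 for ind in top], axis=0)
    votes2 = np.mean([ind.bits2 for ind in top], axis=0)
    keep1 = votes1 > consensus_threshold
    keep2 = votes2 > consensus_threshold
    signs: dict[tuple[str, str], str] = {}
    if master.n_unknown:
        sign_votes = np.mean([ind.signbits for ind in top], axis=0)
        for j, i in enumerate(master.unknown_idx):
            r = master.records[i]
            if sign_votes[j] == 0.5:
                log.warning("sign tie for %s->%s; defaulting to activation",
                            r.source, r.target)
            signs[(r.source, r.target)] = (
                ACTIVATION if sign_votes[j] >= 0.5 else INHIBITION)
    resolved = []
    for r in master.records:
        if r.sign == UNKNOWN:
            resolved.append(signs[(r.source, r.target)])
        else:
            resolved.append(r.sign)
    nets = []
    for keep in (keep1, keep2):
        edges = [(r.source, r.target, resolved[i])
                 for i, r in enumerate(master.records) if keep[i]]
        nets.append(SignedNetwork(master.genes, edges))
    return nets[0], nets[1], signs
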