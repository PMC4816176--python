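"""Planted-truth instance generator for the whole pipeline.

Real runs of the method start from a curated interaction map, a two-group
expression experiment, and a drug-target table.  This module fabricates all
three with a known ground truth so that every stage can be tested end to
end without external data:

* a random signed digraph (the master map) with a stated fraction of its
  edge signs hidden as "unknown";
* two *true* phenotype networks, each a random pruning of the master;
* one fixed point of each true network, chosen so the two phenotype
  patterns disagree on at least 25 % of the genes — these are the planted
  ON/OFF patterns;
* replicate expression values drawn around an ON level (mean 10) and an
  OFF level (mean 2) with Gaussian noise;
* a drug table with one *planted* effective drug — its targets are the
  best-scoring perturbation combination found by exhaustive scan up to
  size 3 — plus decoy drugs with random targets.

ON/OFF expression levels of 10 vs 2 with unit noise give the t-test stage
realistic but essentially saturated power at a handful of replicates; the
noise SD is a parameter so power can be degraded deliberately.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .boolnet import (ACTIVATION, INHIBITION, SignedNetwork,
                      batch_majority_update)
from .circuits import CandidateSet, candidate_genes
from .io_formats import (UNKNOWN, DrugTargetTable, ExpressionDataset,
                         InteractionRecord, write_drug_targets,
                         write_expression, write_interaction_map)
from .perturb import ScanConfig, scan_multitarget
from .preprocess import PhenotypePattern

log = logging.getLogger(__name__)

ON_LEVEL = 10.0
OFF_LEVEL = 2.0

PLANTED_DRUG = "planted_drug"


class GenerationError(RuntimeError):
    """No acceptable instance found within the rejection budget."""


@dataclass
class PlantedInstance:
    """A synthetic pipeline input with full ground truth attached."""

    genes: list[str]
    master: list[InteractionRecord]
    true_signs: dict[tuple[str, str], str]  # unknown-sign edges only
    true_net1: SignedNetwork
    true_net2: SignedNetwork
    patternA: PhenotypePattern
    patternB: PhenotypePattern
    expression: ExpressionDataset
    drugs: DrugTargetTable
    planted_targets: tuple[str, ...]
    planted_gec: int
    candidates: CandidateSet
    seed: int

    @property
    def n_unknown(self) -> int:
        return len(self.true_signs)


def enumerate_states(n: int) -> np.ndarray:
    """All 2**n binary states as a boolean matrix (rows = states)."""
    if n > 20:
        raise ValueError("exhaustive state enumeration limited to 20 genes")
    idx = np.arange(2 ** n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(bool)


def exhaustive_fixed_points(net: SignedNetwork) -> np.ndarray:
    """All fixed points of the majority dynamics (rows), by enumeration."""
    states = enumerate_states(net.n_genes)
    nxt = batch_majority_update(net, states)
    return states[(nxt == states).all(axis=1)]


def _random_master(rng: np.random.Generator, n_genes: int,
                   edge_density: float, frac_inhibition: float,
                   frac_unknown: float
                   ) -> tuple[list[str], list[InteractionRecord],
                              dict[tuple[str, str], str]]:
    genes = [f"G{i:02d}" for i in range(n_genes)]
    pairs = [(s, t) for s in genes for t in genes]
    mask = rng.random(len(pairs)) < edge_density
    edges = [p for p, m in zip(pairs, mask) if m]
    records: list[InteractionRecord] = []
    true_signs: dict[tuple[str, str], str] = {}
    n_unknown = round(frac_unknown * len(edges))
    unknown_set = set(
        rng.choice(len(edges), size=n_unknown, replace=False).tolist()
    ) if n_unknown else set()
    for i, (s, t) in enumerate(edges):
        sign = INHIBITION if rng.random() < frac_inhibition else ACTIVATION
        if i in unknown_set:
            true_signs[(s, t)] = sign
            records.append(InteractionRecord(s, t, UNKNOWN))
        else:
            records.append(InteractionRecord(s, t, sign))
    return genes, records, true_signs


def _prune(records: list[InteractionRecord],
           true_signs: dict[tuple[str, str], str],
           genes: list[str], prune_frac: float,
           rng: np.random.Generator) -> tuple[SignedNetwork, list[int]]:
    n_prune = round(prune_frac * len(records))
    drop = set(rng.choice(len(records), size=n_prune,
                          replace=False).tolist()) if n_prune else set()
    edges = []
    for i, r in enumerate(records):
        if i in drop:
            continue
        sign = true_signs[(r.source, r.target)] if r.sign == UNKNOWN \
            else r.sign
        edges.append((r.source, r.target, sign))
    return SignedNetwork(genes, edges), sorted(drop)


def _best_pattern_pair(net1: SignedNetwork, net2: SignedNetwork,
                       min_diff: int
                       ) -> tuple[np.ndarray, np.ndarray] | None:
    fps1 = exhaustive_fixed_points(net1)
    fps2 = exhaustive_fixed_points(net2)
    if not len(fps1) or not len(fps2):
        return None
    # Hamming distances between every fixed-point pair at once.
    d = (fps1[:, None, :] != fps2[None, :, :]).sum(axis=2)
    i, j = np.unravel_index(int(d.argmax()), d.shape)
    if d[i, j] < min_diff:
        return None
    return fps1[i], fps2[j]


def generate(n_genes: int = 15, edge_density: float = 0.15,
             frac_inhibition: float = 0.25, frac_unknown: float = 0.3,
             prune_frac: float = 0.1, n_replicates: int = 4,
             noise_sd: float = 1.0, n_decoy_drugs: int = 10,
             seed: int = 0, planted_size: int = 3,
             max_attempts: int = 100) -> PlantedInstance:
    """Draw a planted instance; reject and reseed until all invariants hold.

    An attempt is rejected when either pruned network lacks a fixed point,
    when no fixed-point pair differs in at least 25 % of the genes, or when
    the differential topology yields no perturbation candidates.
    """
    if n_genes > 50:
        raise ValueError("generator limited to 50 genes")
    if n_genes > 20:
        raise ValueError(
            "guided fixed-point search beyond 20 genes not implemented; "
            "use n_genes <= 20")
    min_diff = math.ceil(0.25 * n_genes)
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        genes, records, true_signs = _random_master(
            rng, n_genes, edge_density, frac_inhibition, frac_unknown)
        if len(records) < 2:
            continue
        net1, _ = _prune(records, true_signs, genes, prune_frac, rng)
        net2, _ = _prune(records, true_signs, genes, prune_frac, rng)
        pair = _best_pattern_pair(net1, net2, min_diff)
        if pair is None:
            continue
        p1, p2 = pair
        patternA = PhenotypePattern("A", dict(zip(genes, map(bool, p1))))
        patternB = PhenotypePattern("B", dict(zip(genes, map(bool, p2))))
        cands = candidate_genes(net1, net2, patternA, patternB)
        if not cands:
            continue
        # Exhaustive scan up to the planted size gives the exact optimum.
        results = scan_multitarget(
            net2, cands, initial=patternB, reference=patternA,
            cfg=ScanConfig(max_size=planted_size,
                           max_per_size=10 ** 6, seed=seed))
        best = results[0]
        expression = _expression_matrix(rng, genes, patternA, patternB,
                                        n_replicates, noise_sd)
        drugs = _drug_table(rng, genes, best.combination, n_decoy_drugs)
        log.info("instance accepted on attempt %d: %d edges, %d unknown, "
                 "planted combination %s (gec %d)", attempt, len(records),
                 len(true_signs), best.combination, best.gec)
        return PlantedInstance(
            genes=genes, master=records, true_signs=true_signs,
            true_net1=net1, true_net2=net2,
            patternA=patternA, patternB=patternB,
            expression=expression, drugs=drugs,
            planted_targets=best.combination, planted_gec=best.gec,
            candidates=cands, seed=seed)
    raise GenerationError(
        f"no acceptable instance in {max_attempts} attempts "
        f"(n_genes={n_genes}, density={edge_density}, "
        f"prune_frac={prune_frac})")


def _expression_matrix(rng: np.random.Generator, genes: list[str],
                       patternA: PhenotypePattern, patternB: PhenotypePattern,
                       n_replicates: int, noise_sd: float
                       ) -> ExpressionDataset:
    samples = [f"A{r + 1}" for r in range(n_replicates)] + \
        [f"B{r + 1}" for r in range(n_replicates)]
    labels = {s: s[0] for s in samples}
    means = np.empty((len(genes), 2 * n_replicates))
    for i, g in enumerate(genes):
        means[i, :n_replicates] = ON_LEVEL if patternA.states[g] else OFF_LEVEL
        means[i, n_replicates:] = ON_LEVEL if patternB.states[g] else OFF_LEVEL
    values = means + rng.normal(0.0, noise_sd, size=means.shape) \
        if noise_sd > 0 else means
    return ExpressionDataset(genes=list(genes), samples=samples,
                             values=values, labels=labels)


def _drug_table(rng: np.random.Generator, genes: list[str],
                planted_targets: tuple[str, ...],
                n_decoys: int) -> DrugTargetTable:
    records = [(PLANTED_DRUG, g, "unspecified") for g in planted_targets]
    for k in range(n_decoys):
        size = int(rng.integers(1, 4))
        targets = rng.choice(len(genes), size=size, replace=False)
        for t in sorted(targets):
            records.append((f"decoy_{k:02d}", genes[t], "unspecified"))
    return DrugTargetTable(records)


def write_instance(instance: PlantedInstance, directory: str | Path
                   ) -> dict[str, Path]:
    """Write the instance in the pipeline's input dialects plus a truth JSON.

    Returns the mapping of artifact name to path.  The truth file records
    every unknown-sign edge with its true sign, the planted patterns, the
    pruned-network edge lists and the planted drug, for use by tests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": directory / "map.tsv",
        "expression": directory / "expression.tsv",
        "labels": directory / "labels.tsv",
        "drugs": directory / "drugs.tsv",
        "truth": directory / "truth.json",
    }
    write_interaction_map(instance.master, paths["map"])
    write_expression(instance.expression, paths["expression"],
                     paths["labels"])
    write_drug_targets(instance.drugs, paths["drugs"])
    truth = {
        "seed": instance.seed,
        "genes": instance.genes,
        "unknown_sign_edges": [
            {"source": s, "target": t, "true_sign": sign}
            for (s, t), sign in sorted(instance.true_signs.items())],
        "pattern_A": {g: int(v) for g, v in instance.patternA.states.items()},
        "pattern_B": {g: int(v) for g, v in instance.patternB.states.items()},
        "true_net1_edges": sorted(instance.true_net1.edge_set()),
        "true_net2_edges": sorted(instance.true_net2.edge_set()),
        "planted_drug": PLANTED_DRUG,
        "planted_targets": list(instance.planted_targets),
        "planted_gec": instance.planted_gec,
        "candidate_circuit_genes": instance.candidates.circuit_genes,
        "candidate_solo_genes": instance.candidates.solo_genes,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
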