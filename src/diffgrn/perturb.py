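"""Multitarget perturbation scans under clamped majority-rule dynamics.

A perturbation clamps a set of candidate genes to fixed values — the
sustained, dominant effect of an intervention — and lets the synchronous
dynamics settle into an attractor.  The *gene expression change* score of a
combination is

    gec = (# genes whose attractor state differs from the initial pattern)
          − (# clamped genes),

so trivially "changing" a gene by clamping it contributes nothing.  The
scan enumerates (or uniformly samples, above a size cap) combinations of
circuit-candidate genes of sizes 1..max_size; differentially regulated solo
candidates are perturbed only individually.  Clamp values are taken from
the *reference* phenotype pattern, i.e. each perturbed gene is forced to
its state in the phenotype the simulation tries to reach.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .boolnet import SignedNetwork, find_attractor
from .circuits import CandidateSet
from .preprocess import PhenotypePattern

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Scan limits: sizes 1..max_size, at most max_per_size combinations per
    size (uniform sampling beyond), and the minimal changed fraction deemed
    a significant phenotype reversion."""

    max_size: int = 10
    max_per_size: int = 1_000_000
    target_change: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if self.max_per_size < 1:
            raise ValueError("max_per_size must be >= 1")


@dataclass(frozen=True)
class PerturbationResult:
    combination: tuple[str, ...]
    gec: int
    changed_fraction: float

    @property
    def size(self) -> int:
        return len(self.combination)


def simulate_perturbation(net: SignedNetwork, clamp: Mapping[str, bool],
                          initial: PhenotypePattern,
                          max_steps: int | None = None
                          ) -> PerturbationResult:
    """Clamp genes, run to an attractor, and score the expression change.

    Clamped genes are overridden after every synchronous update (and in the
    initial state).  A gene counts as changed when its attractor state
    differs from its state in ``initial``; for limit cycles the mean cycle
    occupancy decides (> 0.5 ON, < 0.5 OFF, exactly 0.5 counts unchanged).
    """
    unknown = set(clamp) - set(net.genes)
    if unknown:
        raise KeyError(f"clamp genes not in network: {sorted(unknown)}")
    init = net.state_from_pattern(initial.states)
    mask = np.zeros(net.n_genes, dtype=bool)
    vals = np.zeros(net.n_genes, dtype=bool)
    for g, v in clamp.items():
        mask[net.index[g]] = True
        vals[net.index[g]] = bool(v)
    att = find_attractor(net, init, max_steps=max_steps,
                         clamp_mask=mask if clamp else None,
                         clamp_values=vals if clamp else None)
    occ = att.occupancy()
    final_on = occ > 0.5
    final_off = occ < 0.5
    changed = (final_on & ~init) | (final_off & init)
    changed_count = int(changed.sum())
    return PerturbationResult(
        combination=tuple(sorted(clamp)),
        gec=changed_count - len(clamp),
        changed_fraction=changed_count / net.n_genes,
    )


def _combinations_of_size(genes: Sequence[str], k: int, cap: int,
                          rng: np.random.Generator
                          ) -> list[tuple[str, ...]]:
    """All k-subsets when C(m,k) <= cap, else cap distinct uniform samples."""
    m = len(genes)
    total = math.comb(m, k)
    if total <= cap:
        return [tuple(c) for c in itertools.combinations(sorted(genes), k)]
    chosen: set[tuple[str, ...]] = set()
    genes = sorted(genes)
    while len(chosen) < cap:
        idx = rng.choice(m, size=k, replace=False)
        chosen.add(tuple(genes[i] for i in sorted(idx)))
    return sorted(chosen)


def reversion_clamp(combination: Sequence[str],
                    reference: PhenotypePattern) -> dict[str, bool]:
    """Clamp map forcing each gene to its state in the reference phenotype."""
    return {g: reference.states[g] for g in combination}


def scan_multitarget(net: SignedNetwork, candidates: CandidateSet,
                     initial: PhenotypePattern, reference: PhenotypePattern,
                     cfg: ScanConfig = ScanConfig()
                     ) -> list[PerturbationResult]:
    """Scan multitarget combinations and rank them by gec.

    Sizes 1..max_size over circuit genes (exhaustive within the per-size
    cap, uniformly sampled beyond it); solo genes contribute size-1
    combinations only.  Results sort by gec descending, ties by smaller
    size then lexicographic gene tuple.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    rng = np.random.default_rng(cfg.seed)
    results: list[PerturbationResult] = []
    seen: set[tuple[str, ...]] = set()
    for k in range(1, cfg.max_size + 1):
        combos = _combinations_of_size(candidates.circuit_genes, k,
                                       cfg.max_per_size, rng) \
            if len(candidates.circuit_genes) >= k else []
        if k == 1:
            combos = sorted(set(combos)
                            | {(g,) for g in candidates.solo_genes})
        for combo in combos:
            if combo in seen:
                continue
            seen.add(combo)
            clamp = reversion_clamp(combo, reference)
            results.append(simulate_perturbation(net, clamp, initial))
    results.sort(key=lambda r: (-r.gec, r.size, r.combination))
    return results


def single_gene_weights(results: Sequence[PerturbationResult],
                        candidates: CandidateSet) -> dict[str, float]:
    """Per-candidate weight from single-target gec, rescaled to [0, 1].

    min gec -> 0, max -> 1 over all candidates (rank-preserving); if every
    single-gene gec is equal all weights are 1.
    """
    singles = {r.combination[0]: r.gec for r in results if r.size == 1}
    missing = set(candidates.all_genes) - set(singles)
    if missing:
        raise RuntimeError(
            f"scan lacks single-gene results for: {sorted(missing)}")
    gecs = {g: singles[g] for g in candidates.all_genes}
    lo, hi = min(gecs.values()), max(gecs.values())
    if hi == lo:
        return {g: 1.0 for g in gecs}
    return {g: (v - lo) / (hi - lo) for g, v in gecs.items()}


def write_scan(results: Sequence[PerturbationResult],
               path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("genes\tsize\tgec\tchanged_fraction\n")
        for r in results:
            fh.write(f"{','.join(r.combination)}\t{r.size}\t{r.gec}\t"
                     f"{r.changed_fraction!r}\n")


def read_scan(path: str | Path) -> list[PerturbationResult]:
    out = []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("genes\t"):
            raise ValueError(f"{path}: not a scan file")
        for line in fh:
            if not line.strip():
                continue
            genes, _, gec, frac = line.rstrip("\n").split("\t")
            out.append(PerturbationResult(tuple(genes.split(",")),
                                          int(gec), float(frac)))
    return out
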