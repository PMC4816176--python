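"""Self-contained validation experiments on planted synthetic instances.

These are the package's standard benchmark runs: GA recovery of planted
networks and signs, planted-drug recovery through the full enrichment
ranking, and mutation-operator calibration.  They are deliberately small —
15-gene instances, population 100 / 60 generations — so a complete
validation pass stays in the minutes range on one CPU; the qualitative
behavior matches larger configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolnet import find_attractor, pattern_agreement
from .contextualize import GAParams, Individual, MasterMap, contextualize, \
    mutate
from .drugrank import rank_drugs
from .perturb import ScanConfig, scan_multitarget, single_gene_weights
from .synthetic import PLANTED_DRUG, generate


@dataclass
class GARecoveryResult:
    perfect_runs: int            # GA seeds reaching o1 = o2 = 0 consensus
    n_runs: int
    sign_recovery: list[float]   # fraction of planted signs recovered

    @property
    def median_sign_recovery(self) -> float:
        return float(np.median(self.sign_recovery))


def ga_recovery_experiment(instance_seed: int = 1, n_ga_seeds: int = 10,
                           population_size: int = 100,
                           generations: int = 60) -> GARecoveryResult:
    """Contextualize one planted instance with several GA seeds.

    A run counts as *perfect* when both consensus networks reach a fixed
    point identical to their phenotype pattern (agreement 0, cycle length
    1).  Sign recovery is the fraction of originally-unknown edges whose
    consensus sign equals the planted truth.
    """
    inst = generate(seed=instance_seed)
    master = MasterMap(inst.master, genes=inst.genes)
    perfect = 0
    recovery: list[float] = []
    for s in range(n_ga_seeds):
        res = contextualize(
            master, inst.patternA, inst.patternB,
            GAParams(population_size=population_size,
                     generations=generations, seed=instance_seed * 1000 + s))
        ok = True
        for net, pat in ((res.net1, inst.patternA),
                         (res.net2, inst.patternB)):
            init = net.state_from_pattern(pat.states)
            att = find_attractor(net, init)
            if pattern_agreement(att, init) != 0 or len(att) != 1:
                ok = False
        perfect += ok
        recovery.append(float(np.mean(
            [res.consensus_signs[e] == sign
             for e, sign in inst.true_signs.items()])))
    return GARecoveryResult(perfect, n_ga_seeds, recovery)


@dataclass
class DrugRecoveryResult:
    wins: int        # instances where the planted drug attains minimal AUC
    n_instances: int
    planted_aucs: list[float] = field(default_factory=list)
    best_aucs: list[float] = field(default_factory=list)


def drug_recovery_experiment(first_seed: int = 1,
                             n_instances: int = 10,
                             scan_size: int = 3) -> DrugRecoveryResult:
    """Rank the planted drug against its decoys on several instances.

    Each instance is scanned exhaustively up to ``scan_size`` on the true
    disease network; the planted drug wins when no ranked drug has a
    strictly smaller enrichment AUC.
    """
    wins = 0
    planted_aucs, best_aucs = [], []
    for k in range(n_instances):
        seed = first_seed + k
        inst = generate(seed=seed)
        scan = scan_multitarget(inst.true_net2, inst.candidates,
                                initial=inst.patternB,
                                reference=inst.patternA,
                                cfg=ScanConfig(max_size=scan_size,
                                               seed=seed))
        weights = single_gene_weights(scan, inst.candidates)
        df = rank_drugs(inst.drugs, scan, weights, inst.true_net2,
                        initial=inst.patternB, reference=inst.patternA,
                        candidates=inst.candidates)
        aucs = df.set_index("drug")["auc"]
        if PLANTED_DRUG not in aucs.index:
            continue
        planted_aucs.append(float(aucs[PLANTED_DRUG]))
        best_aucs.append(float(aucs.min()))
        if aucs[PLANTED_DRUG] <= aucs.min() + 1e-12:
            wins += 1
    return DrugRecoveryResult(wins, n_instances, planted_aucs, best_aucs)


def mutation_calibration(rate: float = 0.01, n_trials: int = 10_000,
                         n_bits: int = 100, seed: int = 0
                         ) -> dict[str, float]:
    """Empirical flips per subarray vs the Bernoulli-per-bit model.

    Returns the mean observed flips per subarray, the binomial expectation
    ``n_bits * rate`` and the 3-sigma envelope of the empirical mean.
    """
    rng = np.random.default_rng(seed)
    base = Individual(np.zeros(n_bits, bool), np.ones(n_bits, bool),
                      np.zeros(n_bits, bool))
    flips = np.zeros(3)
    for _ in range(n_trials):
        out = mutate(base, rate, rng)
        flips += [out.bits1.sum(), (~out.bits2).sum(), out.signbits.sum()]
    mean = flips / n_trials
    return {
        "mean_flips": float(np.mean(mean)),
        "per_subarray": [float(m) for m in mean],
        "expected": n_bits * rate,
        "three_sigma": float(
            3 * np.sqrt(n_bits * rate * (1 - rate) / n_trials)),
    }
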