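"""Drug-target enrichment over the multitarget combination scan.

Each perturbation candidate g carries a weight w_g — its rescaled
single-target gec.  For drug d and scanned combination i the raw enrichment

    e_{d,i} = sum of w_g over targets of d contained in combination i

is normalized by d's maximum attainable score (the sum of the weights of
all its candidate targets) to give ê_{d,i} in [0, 1].  The ê mass is then
laid out over the grid of distinct gec values of the scan as a probability
mass function, cumulated into a CDF, and summarized by its AUC with unit
step per grid value (the top grid value contributes nothing).  A drug whose
enrichment concentrates entirely in the best-scoring combinations reaches
the optimum AUC_d = 0; an uninformative uniform enrichment gives
(g−1)/2 on a g-point grid.  Rankings report the percent difference from
that uniform baseline — positive = more specific than chance.

Only targets already predicted as perturbation candidates enter the
analysis; drugs with no candidate target are excluded with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .boolnet import SignedNetwork
from .circuits import CandidateSet
from .io_formats import DrugTargetTable
from .perturb import PerturbationResult, reversion_clamp, simulate_perturbation
from .preprocess import PhenotypePattern

log = logging.getLogger(__name__)


@dataclass
class EnrichmentScores:
    drug: str
    raw: np.ndarray         # e_{d,i} per scanned combination
    normalized: np.ndarray  # ê_{d,i} in [0, 1]
    max_attainable: float   # sum of candidate-target weights of the drug


@dataclass
class EnrichmentDistribution:
    """PMF/CDF of a drug's normalized enrichment over the gec grid."""

    grid: np.ndarray  # sorted distinct gec values, ascending
    pmf: np.ndarray
    cdf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cdf = np.cumsum(self.pmf)


class ZeroEnrichmentError(ValueError):
    """The drug's enrichment mass is zero; its distribution is undefined."""


def enrichment_scores(weights: Mapping[str, float],
                      results: Sequence[PerturbationResult],
                      drug: str, targets: Sequence[str]) -> EnrichmentScores:
    """Raw and normalized per-combination enrichment of one drug.

    ``targets`` is restricted to the weighted candidate set; a drug without
    any candidate target cannot be scored.
    """
    cand_targets = sorted(set(targets) & set(weights))
    if not cand_targets:
        raise ZeroEnrichmentError(
            f"drug {drug!r} has no targets among the candidates")
    max_e = float(sum(weights[g] for g in cand_targets))
    tset = set(cand_targets)
    raw = np.array([sum(weights[g] for g in r.combination if g in tset)
                    for r in results])
    normalized = raw / max_e if max_e > 0 else np.zeros_like(raw)
    return EnrichmentScores(drug=drug, raw=raw, normalized=normalized,
                            max_attainable=max_e)


def enrichment_distribution(scores: EnrichmentScores,
                            results: Sequence[PerturbationResult],
                            grid: np.ndarray | None = None
                            ) -> EnrichmentDistribution:
    """Lay the normalized enrichment mass over the gec grid.

    p_d(x) = (sum of ê over combinations with gec == x) / (total ê); the
    grid defaults to the sorted distinct gec values of the scan and should
    be shared across drugs of one run.
    """
    gecs = np.array([r.gec for r in results])
    if grid is None:
        grid = np.unique(gecs)
    total = scores.normalized.sum()
    if total <= 0:
        raise ZeroEnrichmentError(
            f"drug {scores.drug!r} has zero total enrichment")
    pmf = np.array([scores.normalized[gecs == x].sum() for x in grid]) / total
    return EnrichmentDistribution(grid=np.asarray(grid, dtype=float), pmf=pmf)


def auc(dist: EnrichmentDistribution) -> float:
    """CDF area with unit step per grid value, omitting the top value.

    The step *at* the maximum contributes nothing, so a point mass at the
    grid maximum — the optimal enrichment pattern — yields exactly 0, and a
    point mass at the minimum yields g − 1 on a g-point grid.
    """
    if dist.grid.size == 0:
        raise ValueError("empty grid")
    return float(dist.cdf[:-1].sum())


def uniform_auc(n_grid: int) -> float:
    """AUC of the uniform pmf over an n-point grid: (n − 1) / 2."""
    if n_grid < 1:
        raise ValueError("grid must be non-empty")
    return (n_grid - 1) / 2.0


def uniform_comparison(n_grid: int, auc_d: float) -> float:
    """Percent difference from the uniform baseline.

    100 × (AUC_uniform − AUC_d) / AUC_uniform: positive for drugs more
    specific than an uninformative enrichment, negative for worse-than-
    uniform patterns (mass in the poorly-scoring combinations).
    """
    if n_grid < 2:
        raise ValueError("uniform comparison needs a grid of >= 2 values")
    base = uniform_auc(n_grid)
    return 100.0 * (base - auc_d) / base


def drug_clamp(targets: Mapping[str, str],
               reference: PhenotypePattern) -> dict[str, bool]:
    """Clamp map of a whole-drug assay under the dominant-effect assumption.

    ``increases`` clamps ON, ``decreases`` OFF, ``unspecified`` falls back
    to the reference-phenotype state (reversion clamp).
    """
    clamp: dict[str, bool] = {}
    for g, action in targets.items():
        if action == "increases":
            clamp[g] = True
        elif action == "decreases":
            clamp[g] = False
        else:
            clamp[g] = reference.states[g]
    return clamp


def drug_assay(net: SignedNetwork, targets: Mapping[str, str],
               initial: PhenotypePattern, reference: PhenotypePattern,
               candidates: CandidateSet | None = None) -> float:
    """Simulate one drug: clamp all its (candidate) targets simultaneously.

    Returns the changed fraction of the expression program; raises if the
    drug has no target in the network.
    """
    eligible = set(net.genes)
    if candidates is not None:
        eligible &= set(candidates.all_genes)
    targets = {g: a for g, a in targets.items() if g in eligible}
    if not targets:
        raise ZeroEnrichmentError("drug has no targets in the network")
    clamp = drug_clamp(targets, reference)
    return simulate_perturbation(net, clamp, initial).changed_fraction


def rank_drugs(drug_table: DrugTargetTable,
               results: Sequence[PerturbationResult],
               weights: Mapping[str, float],
               net: SignedNetwork,
               initial: PhenotypePattern,
               reference: PhenotypePattern,
               candidates: CandidateSet | None = None) -> pd.DataFrame:
    """Rank every scorable drug by ascending enrichment AUC.

    Columns: n_targets (among candidates), auc, pct_diff_uniform,
    assay_changed_fraction.  Drugs with no candidate targets (or zero
    enrichment mass) are excluded with a warning.
    """
    grid = np.unique([r.gec for r in results]).astype(float)
    rows = []
    for drug in drug_table.drugs:
        targets = drug_table.targets(drug)
        try:
            scores = enrichment_scores(weights, results, drug,
                                       list(targets))
            dist = enrichment_distribution(scores, results, grid=grid)
        except ZeroEnrichmentError as exc:
            log.warning("excluding drug: %s", exc)
            continue
        auc_d = auc(dist)
        pct = uniform_comparison(len(grid), auc_d) if len(grid) >= 2 \
            else float("nan")
        try:
            assay = drug_assay(net, targets, initial, reference, candidates)
        except ZeroEnrichmentError:
            assay = float("nan")
        rows.append({"drug": drug,
                     "n_targets": len(set(targets) & set(weights)),
                     "auc": auc_d,
                     "pct_diff_uniform": pct,
                     "assay_changed_fraction": assay})
    df = pd.DataFrame(rows, columns=["drug", "n_targets", "auc",
                                     "pct_diff_uniform",
                                     "assay_changed_fraction"])
    if not df.empty:
        df = df.sort_values(["auc", "drug"], kind="stable") \
               .reset_index(drop=True)
    return df


def write_ranking(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
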