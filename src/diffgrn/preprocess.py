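"""Differential-expression gene selection and ON/OFF binarization.

The pipeline starts from a gene x sample expression matrix with a two-group
phenotype labeling.  Genes that separate the two phenotypes — Welch
two-sample t-test p-value below ``p_cutoff`` AND absolute linear fold change
above ``fc_cutoff`` — define the working gene set.  Each selected gene is
then binarized per phenotype: the phenotype with the higher group mean is
ON, the other OFF, yielding the two target expression patterns the network
contextualization must reproduce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionDataset

log = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class DECutoffs:
    """Differential-expression cutoffs.

    p_cutoff: raw (uncorrected) significance level; fc_cutoff: minimum
    fold change on the linear scale (>= 1).  An optional Benjamini-Hochberg
    correction can be switched on; it defaults off because the selection is
    defined on raw p-values.
    """

    p_cutoff: float = 0.05
    fc_cutoff: float = 2.0
    bh_fdr: bool = False
    log_scale: bool = False  # inputs are log2; fold change = 2**|Δmean|

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")


@dataclass
class PhenotypePattern:
    """Binary ON/OFF state per gene for one phenotype."""

    phenotype: str
    states: dict[str, bool]

    @property
    def genes(self) -> list[str]:
        return list(self.states)

    def vector(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self.states[g] for g in genes], dtype=bool)

    def on_genes(self) -> set[str]:
        return {g for g, s in self.states.items() if s}


def welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values with an epsilon variance guard.

    Genes with zero variance in both groups get the guard variance so that
    distinct means give p ~ 0 and equal means p = 1 instead of NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va < _VAR_EPS) & (vb < _VAR_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        pvals = np.where(degenerate, np.where(same, 1.0, 0.0), pvals)
    return np.nan_to_num(pvals, nan=1.0)


def fold_changes(a: np.ndarray, b: np.ndarray,
                 log_scale: bool = False) -> np.ndarray:
    """Row-wise absolute fold change (always >= 1) between group means."""
    ma = np.asarray(a, dtype=float).mean(axis=1)
    mb = np.asarray(b, dtype=float).mean(axis=1)
    if log_scale:
        return 2.0 ** np.abs(ma - mb)
    ratio = (np.abs(ma) + _VAR_EPS) / (np.abs(mb) + _VAR_EPS)
    return np.maximum(ratio, 1.0 / ratio)


def differential_genes(data: ExpressionDataset,
                       cutoffs: DECutoffs = DECutoffs()) -> list[str]:
    """Genes passing both the Welch t-test and the fold-change filter.

    Returns the selected genes in input order.  The result is invariant to
    sample column order and to swapping the two phenotype labels.
    """
    pa, pb = data.phenotypes
    a = data.group_matrix(pa)
    b = data.group_matrix(pb)
    pvals = welch_pvalues(a, b)
    if cutoffs.bh_fdr:
        pvals = _bh_adjust(pvals)
    fc = fold_changes(a, b, log_scale=cutoffs.log_scale)
    keep = (pvals < cutoffs.p_cutoff) & (fc > cutoffs.fc_cutoff)
    return [g for g, k in zip(data.genes, keep) if k]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def binarize(data: ExpressionDataset,
             genes: Sequence[str] | None = None
             ) -> tuple[PhenotypePattern, PhenotypePattern]:
    """Binarize each gene: higher-mean phenotype ON, the other OFF.

    A tie in group means binarizes to OFF in both phenotypes and is logged
    as ambiguous.
    """
    if genes is None:
        genes = data.genes
    unknown = set(genes) - set(data.genes)
    if unknown:
        raise KeyError(f"genes not in dataset: {sorted(unknown)}")
    pa, pb = data.phenotypes
    idx = {g: i for i, g in enumerate(data.genes)}
    ma = data.group_matrix(pa).mean(axis=1)
    mb = data.group_matrix(pb).mean(axis=1)
    states_a: dict[str, bool] = {}
    states_b: dict[str, bool] = {}
    for g in genes:
        i = idx[g]
        if np.isclose(ma[i], mb[i]):
            log.warning("gene %s: equal group means; binarized OFF/OFF", g)
            states_a[g] = states_b[g] = False
        else:
            states_a[g] = ma[i] > mb[i]
            states_b[g] = mb[i] > ma[i]
    return (PhenotypePattern(pa, states_a), PhenotypePattern(pb, states_b))


def write_patterns(patterns: tuple[PhenotypePattern, PhenotypePattern],
                   path: str | Path) -> None:
    pa, pb = patterns
    with Path(path).open("w") as fh:
        fh.write(f"gene\tstate_{pa.phenotype}\tstate_{pb.phenotype}\n")
        for g in pa.genes:
            fh.write(f"{g}\t{int(pa.states[g])}\t{int(pb.states[g])}\n")


def read_patterns(path: str | Path
                  ) -> tuple[PhenotypePattern, PhenotypePattern]:
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 3 or header[0] != "gene":
            raise ValueError(f"{path}: not a pattern file")
        name_a = header[1].removeprefix("state_")
        name_b = header[2].removeprefix("state_")
        states_a: dict[str, bool] = {}
        states_b: dict[str, bool] = {}
        for line in fh:
            if not line.strip():
                continue
            g, sa, sb = line.rstrip("\n").split("\t")
            states_a[g] = bool(int(sa))
            states_b[g] = bool(int(sb))
    return (PhenotypePattern(name_a, states_a),
            PhenotypePattern(name_b, states_b))
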