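"""Readers/writers for the pipeline's tabular formats and retention bookkeeping.

Formats
-------
* signed-edge TSV: ``source <tab> target <tab> sign`` with sign tokens
  ``+`` (activation), ``-`` (inhibition), ``?`` (unknown); optional header
  detected by a first field equal to ``source``;
* expression TSV: rows = genes, header row = sample ids, plus a two-column
  label TSV mapping each sample to one of two phenotypes;
* drug-target TSV: ``drug <tab> gene <tab> action`` with action in
  ``increases`` / ``decreases`` / ``unspecified`` (blank = unspecified).

Gene symbols are case-sensitive and used verbatim; no alias resolution is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"
UNKNOWN = "unknown"

_SIGN_OF_TOKEN = {"+": ACTIVATION, "-": INHIBITION, "?": UNKNOWN}
_TOKEN_OF_SIGN = {v: k for k, v in _SIGN_OF_TOKEN.items()}

_ACTIONS = {"increases", "decreases", "unspecified"}


class ParseError(ValueError):
    """Malformed input line; the message names the offending line number."""


class ConsistencyError(ValueError):
    """Contradictory records for the same key (e.g. edge signed + and -)."""


class LabelingError(ValueError):
    """Expression samples and phenotype labels do not match up."""


class UndefinedRetentionError(ZeroDivisionError):
    """Retention is undefined for an empty reference edge set."""


@dataclass(frozen=True)
class InteractionRecord:
    source: str
    target: str
    sign: str  # activation | inhibition | unknown

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("gene symbols must be non-empty")
        if self.sign not in _TOKEN_OF_SIGN:
            raise ValueError(f"invalid sign {self.sign!r}")


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a two-group phenotype labeling."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    labels: dict[str, str]  # sample -> phenotype

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample lists")
        if np.isnan(self.values).any():
            raise ParseError("expression matrix contains missing values")
        missing = [s for s in self.samples if s not in self.labels]
        if missing:
            raise LabelingError(f"samples without phenotype label: {missing}")
        phenos = self.phenotypes
        if len(phenos) != 2:
            raise LabelingError(
                f"expected exactly 2 phenotypes, got {sorted(phenos)}")
        for p in phenos:
            if len(self.sample_columns(p)) < 2:
                raise LabelingError(
                    f"phenotype {p!r} has <2 replicate samples")

    @property
    def phenotypes(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.labels[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_columns(self, phenotype: str) -> list[int]:
        return [i for i, s in enumerate(self.samples)
                if self.labels[s] == phenotype]

    def group_matrix(self, phenotype: str) -> np.ndarray:
        return self.values[:, self.sample_columns(phenotype)]


def read_interaction_map(path: str | Path) -> list[InteractionRecord]:
    """Load a signed-edge TSV, deduplicating repeated edges.

    Duplicate (source, target) lines collapse to one record; a known sign
    overrides ``?``, while two contradictory known signs raise
    :class:`ConsistencyError`.  Input order of first occurrence is kept so
    downstream edge indexing is deterministic.
    """
    path = Path(path)
    records: dict[tuple[str, str], InteractionRecord] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}")
            source, target, token = (p.strip() for p in parts)
            if lineno == 1 and source.lower() == "source":
                continue  # header row
            if token not in _SIGN_OF_TOKEN:
                raise ParseError(
                    f"{path}:{lineno}: invalid sign token {token!r} "
                    f"(expected +, - or ?)")
            rec = InteractionRecord(source, target, _SIGN_OF_TOKEN[token])
            key = (source, target)
            if key in records:
                old = records[key]
                if old.sign == rec.sign or rec.sign == UNKNOWN:
                    continue
                if old.sign == UNKNOWN:
                    records[key] = rec
                else:
                    raise ConsistencyError(
                        f"{path}:{lineno}: edge {source}->{target} has "
                        f"conflicting signs {old.sign} and {rec.sign}")
            else:
                records[key] = rec
    return list(records.values())


def write_interaction_map(records: Iterable[InteractionRecord],
                          path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tsign\n")
        for r in records:
            fh.write(f"{r.source}\t{r.target}\t{_TOKEN_OF_SIGN[r.sign]}\n")


def read_expression(path: str | Path,
                    label_path: str | Path) -> ExpressionDataset:
    """Load an expression TSV (rows = genes) and its sample-label TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: expression matrix contains NA values")
    ldf = pd.read_csv(label_path, sep="\t", header=None,
                      names=["sample", "phenotype"], dtype=str)
    labels = dict(zip(ldf["sample"], ldf["phenotype"]))
    return ExpressionDataset(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def write_expression(data: ExpressionDataset, path: str | Path,
                     label_path: str | Path) -> None:
    df = pd.DataFrame(data.values, index=data.genes, columns=data.samples)
    df.to_csv(path, sep="\t", index_label="gene")
    with Path(label_path).open("w") as fh:
        for s in data.samples:
            fh.write(f"{s}\t{data.labels[s]}\n")


@dataclass
class DrugTargetTable:
    """Drug -> gene target records with mode of action."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dedup: dict[tuple[str, str], str] = {}
        for drug, gene, action in self.records:
            if action not in _ACTIONS:
                raise ValueError(f"invalid action {action!r}")
            key = (drug, gene)
            if key in dedup and dedup[key] != action:
                log.warning("conflicting actions for %s->%s; keeping %s",
                            drug, gene, dedup[key])
                continue
            dedup[key] = action
        self.records = [(d, g, a) for (d, g), a in dedup.items()]

    @property
    def drugs(self) -> list[str]:
        seen: list[str] = []
        for d, _, _ in self.records:
            if d not in seen:
                seen.append(d)
        return seen

    def targets(self, drug: str) -> dict[str, str]:
        """gene -> action for one drug."""
        return {g: a for d, g, a in self.records if d == drug}


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 fields, "
                    f"got {len(parts)}")
            if lineno == 1 and parts[0].strip().lower() == "drug":
                continue
            drug, gene = parts[0].strip(), parts[1].strip()
            action = parts[2].strip() if len(parts) == 3 and parts[2].strip() \
                else "unspecified"
            if action not in _ACTIONS:
                raise ParseError(
                    f"{path}:{lineno}: invalid action {action!r}")
            records.append((drug, gene, action))
    return DrugTargetTable(records)


def write_drug_targets(table: DrugTargetTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("drug\tgene\taction\n")
        for drug, gene, action in table.records:
            fh.write(f"{drug}\t{gene}\t{action}\n")


def retention_fraction(raw: set, contextualized: set) -> float:
    """Percentage of reference edges kept after contextualization.

    ``100 * |raw ∩ contextualized| / |raw|``, full precision; round to one
    decimal for reporting.  Undefined (error) for an empty reference set,
    where a retention table prints a dash.
    """
    if not raw:
        raise UndefinedRetentionError(
            "retention undefined for empty reference edge set")
    return 100.0 * len(set(raw) & set(contextualized)) / len(raw)


def retention_from_counts(raw: int, kept: int) -> float:
    """Retention percentage straight from raw/kept interaction counts."""
    if raw <= 0:
        raise UndefinedRetentionError(
            "retention undefined for zero reference interactions")
    if kept > raw or kept < 0:
        raise ValueError("kept count must lie in [0, raw]")
    return 100.0 * kept / raw


def retention_table(columns: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Retention bookkeeping over several (raw, kept) count columns.

    Returns a DataFrame with raw, kept, and retained-% rows (one decimal,
    NaN for undefined 0-interaction columns) and an attached full-precision
    mean over the defined columns in ``df.attrs['mean_retained']``.
    """
    raws, keps, rets = {}, {}, {}
    for name, (raw, kept) in columns.items():
        raws[name], keps[name] = raw, kept
        try:
            rets[name] = round(retention_from_counts(raw, kept), 1)
        except UndefinedRetentionError:
            rets[name] = float("nan")
    df = pd.DataFrame({"raw": raws, "kept": keps, "retained_pct": rets}).T
    defined = [retention_from_counts(*columns[n]) for n in columns
               if columns[n][0] > 0]
    df.attrs["mean_retained"] = float(np.mean(defined)) if defined else None
    return df
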