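"""End-to-end orchestration: differential expression -> binarization ->
GA contextualization -> circuit analysis -> perturbation scan -> drug
ranking, with a structured JSON run report.

Every stage writes its output to disk in the package's plain-text dialects,
so any suffix of the pipeline can be resumed from the files alone.  One
global seed deterministically derives the per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .boolnet import SignedNetwork
from .circuits import candidate_genes
from .contextualize import (ContextualizationResult, GAParams, MasterMap,
                            contextualize)
from .drugrank import rank_drugs, write_ranking
from .io_formats import (InteractionRecord, read_drug_targets,
                         read_expression, read_interaction_map,
                         write_interaction_map)
from .perturb import ScanConfig, scan_multitarget, single_gene_weights, \
    write_scan
from .preprocess import DECutoffs, binarize, differential_genes, \
    write_patterns

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

_KNOWN_KEYS = {"expression", "labels", "map", "drugs", "outdir", "seed",
               "de", "ga", "scan", "max_circuit_length"}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    expression: str
    labels: str
    map: str
    outdir: str
    drugs: str | None = None
    seed: int = 0
    de: DECutoffs = field(default_factory=DECutoffs)
    ga: GAParams | None = None
    scan: ScanConfig | None = None
    max_circuit_length: int | None = None

    def __post_init__(self) -> None:
        # one global seed drives every stochastic stage deterministically
        ss = np.random.SeedSequence(self.seed).spawn(2)
        ga_seed, scan_seed = (int(s.generate_state(1)[0] % 2 ** 31)
                              for s in ss)
        if self.ga is None:
            self.ga = GAParams(seed=ga_seed)
        elif self.ga.seed == 0:
            self.ga = GAParams(**{**asdict(self.ga), "seed": ga_seed})
        if self.scan is None:
            self.scan = ScanConfig(seed=scan_seed)
        elif self.scan.seed == 0:
            self.scan = ScanConfig(**{**asdict(self.scan),
                                      "seed": scan_seed})

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "de" in raw:
            raw["de"] = DECutoffs(**raw["de"])
        if "ga" in raw:
            raw["ga"] = GAParams(**raw["ga"])
        if "scan" in raw:
            raw["scan"] = ScanConfig(**raw["scan"])
        return RunConfig(**raw)


def select_master(records: list[InteractionRecord],
                  selected_genes: list[str]) -> MasterMap:
    """Restrict a literature map to the selected genes.

    Keeps only edges whose both endpoints were selected; the master gene
    universe is the selected genes that touch at least one kept edge, in
    selection order (isolated genes carry no regulatory information for
    the Boolean model).
    """
    selected = set(selected_genes)
    kept = [r for r in records
            if r.source in selected and r.target in selected]
    if not kept:
        raise RuntimeError("no interactions among the selected genes")
    touched = {g for r in kept for g in (r.source, r.target)}
    return MasterMap(kept, genes=[g for g in selected_genes
                                  if g in touched])


def _edge_stats(net1: SignedNetwork, net2: SignedNetwork) -> dict:
    """Common/specific interaction accounting between the two networks."""
    e1, e2 = net1.edge_set(), net2.edge_set()
    common = e1 & e2
    stats = {"common": len(common)}
    for k, edges in (("phenotype1", e1), ("phenotype2", e2)):
        specific = len(edges) - len(common)
        stats[f"{k}_total"] = len(edges)
        stats[f"{k}_specific"] = specific
        stats[f"{k}_specific_ratio"] = (
            round(100.0 * specific / len(edges), 1) if edges else None)
    return stats


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the JSON run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "package_version": __version__,
                    "seed": config.seed,
                    "stages": {}}

    log.info("stage 1/6: differential expression")
    data = read_expression(config.expression, config.labels)
    de_genes = differential_genes(data, config.de)
    if not de_genes:
        raise RuntimeError("differential expression selected no genes; "
                           "relax the cutoffs")
    patternA, patternB = binarize(data, de_genes)
    write_patterns((patternA, patternB), outdir / "patterns.tsv")
    report["stages"]["diffexp"] = {
        "n_genes_input": len(data.genes), "n_genes_selected": len(de_genes),
        "p_cutoff": config.de.p_cutoff, "fc_cutoff": config.de.fc_cutoff}

    log.info("stage 2/6: contextualization GA")
    master = select_master(read_interaction_map(config.map), de_genes)
    # patterns restricted to master genes
    pa = type(patternA)(patternA.phenotype,
                        {g: patternA.states[g] for g in master.genes})
    pb = type(patternB)(patternB.phenotype,
                        {g: patternB.states[g] for g in master.genes})
    result = contextualize(master, pa, pb, config.ga)
    _write_net(result.net1, outdir / "net_A.tsv")
    _write_net(result.net2, outdir / "net_B.tsv")
    best = result.best_objectives
    report["stages"]["contextualize"] = {
        "n_master_edges": master.n_edges,
        "n_unknown_signs": master.n_unknown,
        "best_objectives": list(best),
        "network_stats": _edge_stats(result.net1, result.net2),
    }

    log.info("stage 3/6: circuit and differential-regulation analysis")
    cands = candidate_genes(result.net1, result.net2, pa, pb,
                            max_circuit_length=config.max_circuit_length)
    (outdir / "candidates.tsv").write_text(
        "gene\tclass\n"
        + "".join(f"{g}\tcircuit\n" for g in cands.circuit_genes)
        + "".join(f"{g}\tsolo\n" for g in cands.solo_genes))
    report["stages"]["candidates"] = {
        "circuit_genes": cands.circuit_genes,
        "solo_genes": cands.solo_genes}
    if not cands:
        report["status"] = "no_candidates"
        _dump(report, outdir)
        return report

    log.info("stage 4/6: multitarget perturbation scan")
    scan = scan_multitarget(result.net2, cands, initial=pb, reference=pa,
                            cfg=config.scan)
    write_scan(scan, outdir / "combos.tsv")
    top = scan[0]
    report["stages"]["perturb"] = {
        "n_combinations": len(scan),
        "top_combination": list(top.combination),
        "top_gec": top.gec,
        "top_changed_fraction": top.changed_fraction,
        "reaches_target_change": top.changed_fraction
        >= config.scan.target_change,
    }

    log.info("stage 5/6: single-gene weights")
    weights = single_gene_weights(scan, cands)
    report["stages"]["weights"] = {g: round(w, 6)
                                   for g, w in weights.items()}

    if config.drugs is None:
        log.warning("no drug table supplied; stopping after the scan")
        report["status"] = "partial_no_drug_table"
        _dump(report, outdir)
        return report

    log.info("stage 6/6: drug enrichment ranking")
    table = read_drug_targets(config.drugs)
    ranking = rank_drugs(table, scan, weights, result.net2,
                         initial=pb, reference=pa, candidates=cands)
    write_ranking(ranking, outdir / "ranking.tsv")
    report["stages"]["drugs"] = {
        "n_drugs_in_table": len(table.drugs),
        "n_drugs_ranked": len(ranking),
        "ranking": ranking.to_dict(orient="records"),
    }
    report["status"] = "complete"
    _dump(report, outdir)
    return report


def _write_net(net: SignedNetwork, path: Path) -> None:
    write_interaction_map(
        [InteractionRecord(e.source, e.target, e.sign) for e in net.edges],
        path)


def _dump(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
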