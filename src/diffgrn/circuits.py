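"""Differential network topology: circuits and perturbation candidates.

Elementary circuits (directed cycles visiting each intermediate node once,
self-loops included) are the stability determinants of a Boolean GRN:
positive circuits (even number of inhibitions) support multistability,
negative circuits (odd number) oscillation.  Candidate genes for
perturbation are

* genes lying on circuits *common* to the two phenotype-specific networks
  (same node sequence and same edge signs) — combinable targets; and
* genes under *differential regulation* — whose sets of expressed
  regulators differ between the two networks — perturbable only
  individually.

Enumeration uses Johnson's algorithm (via :func:`networkx.simple_cycles`),
whose output is exponential in the worst case; an optional length cap keeps
large dense networks tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .boolnet import INHIBITION, SignedNetwork
from .preprocess import PhenotypePattern

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Circuit:
    """An elementary circuit in canonical rotation.

    ``nodes`` starts at the lexicographically smallest gene of the cycle;
    ``edges`` are the signed edges traversed in order; ``sign`` is the
    parity of the inhibition count.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]

    @property
    def sign(self) -> str:
        n_inh = sum(1 for _, _, s in self.edges if s == INHIBITION)
        return NEGATIVE if n_inh % 2 else POSITIVE

    def __len__(self) -> int:
        return len(self.nodes)

    @staticmethod
    def from_cycle(cycle: Sequence[str], net: SignedNetwork) -> "Circuit":
        """Canonicalize a node cycle and attach the traversed edge signs."""
        cycle = list(cycle)
        k = cycle.index(min(cycle))
        rot = tuple(cycle[k:] + cycle[:k])
        sign_of = {(e.source, e.target): e.sign for e in net.edges}
        edges = tuple(
            (rot[i], rot[(i + 1) % len(rot)],
             sign_of[(rot[i], rot[(i + 1) % len(rot)])])
            for i in range(len(rot)))
        return Circuit(nodes=rot, edges=edges)


@dataclass
class CandidateSet:
    """Perturbation candidates split into combinable and solo genes."""

    circuit_genes: list[str]
    solo_genes: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.circuit_genes) & set(self.solo_genes)
        if overlap:
            raise ValueError(f"solo/circuit overlap: {sorted(overlap)}")

    @property
    def all_genes(self) -> list[str]:
        return self.circuit_genes + self.solo_genes

    def __bool__(self) -> bool:
        return bool(self.circuit_genes or self.solo_genes)


def elementary_circuits(net: SignedNetwork,
                        max_length: int | None = None) -> list[Circuit]:
    """All elementary circuits of the network, each in canonical form.

    ``max_length`` caps the circuit length (logged when active); ``None``
    enumerates everything.  An acyclic network yields an empty list.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.genes)
    g.add_edges_from((e.source, e.target) for e in net.edges)
    if max_length is not None:
        log.info("circuit enumeration capped at length %d", max_length)
    circuits = [Circuit.from_cycle(c, net)
                for c in nx.simple_cycles(g, length_bound=max_length)]
    circuits.sort(key=lambda c: (len(c), c.nodes))
    return circuits


def circuit_sign(c: Circuit) -> str:
    """Parity classification: even inhibitions positive, odd negative."""
    return c.sign


def common_circuits(circuits1: Iterable[Circuit],
                    circuits2: Iterable[Circuit]) -> list[Circuit]:
    """Circuits identical in both networks (node sequence AND edge signs).

    Because sign assignments are shared between the two contextualized
    networks, requiring equal signs only excludes circuits whose edges are
    differently resolved; a node-path-only looser rule would differ exactly
    when signs diverge, which is logged.
    """
    circuits1 = list(circuits1)
    by_key = {(c.nodes, c.edges): c for c in circuits1}
    paths1 = {c.nodes for c in circuits1}
    out = []
    for c in circuits2:
        if (c.nodes, c.edges) in by_key:
            out.append(c)
        elif c.nodes in paths1:
            log.info("circuit %s shares its node path but not its signs "
                     "between the two networks; excluded", "->".join(c.nodes))
    out.sort(key=lambda c: (len(c), c.nodes))
    return out


def differentially_regulated(net1: SignedNetwork, net2: SignedNetwork,
                             patternA: PhenotypePattern,
                             patternB: PhenotypePattern) -> list[str]:
    """Genes whose sets of *expressed* regulators differ between networks.

    Regulator sets are constrained to genes ON in the respective phenotype
    pattern, since an unexpressed regulator cannot contribute to its
    target's expression.
    """
    genes = sorted(set(net1.genes) | set(net2.genes))
    on_a = patternA.on_genes()
    on_b = patternB.on_genes()
    out = []
    for g in genes:
        regs1 = {s for s, _ in net1.regulators(g)} & on_a \
            if g in net1.index else set()
        regs2 = {s for s, _ in net2.regulators(g)} & on_b \
            if g in net2.index else set()
        if regs1 != regs2:
            out.append(g)
    return out


def candidate_genes(net1: SignedNetwork, net2: SignedNetwork,
                    patternA: PhenotypePattern, patternB: PhenotypePattern,
                    max_circuit_length: int | None = None) -> CandidateSet:
    """Assemble the perturbation-candidate set from both networks.

    circuit_genes: union of genes on common circuits (positive and
    negative alike); solo_genes: differentially regulated genes not
    already on a common circuit.
    """
    c1 = elementary_circuits(net1, max_length=max_circuit_length)
    c2 = elementary_circuits(net2, max_length=max_circuit_length)
    common = common_circuits(c1, c2)
    circ_genes = sorted({g for c in common for g in c.nodes})
    diff = differentially_regulated(net1, net2, patternA, patternB)
    solo = [g for g in diff if g not in set(circ_genes)]
    return CandidateSet(circuit_genes=circ_genes, solo_genes=solo)
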