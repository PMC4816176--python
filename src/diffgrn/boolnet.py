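"""Boolean gene-regulatory-network semantics under the majority rule.

A gene regulatory network (GRN) is a directed graph whose edges are signed
(activation or inhibition).  The dynamics are Boolean and fully synchronous:
every gene is updated simultaneously at each time step.  The update rule is
the *majority rule*:

* a gene turns ON iff its ON activators strictly outnumber its ON inhibitors;
* a tie (including "no active regulator") yields OFF;
* a gene with no incoming edges at all is constitutively ON.

Synchronous Boolean dynamics on a finite state space always end in an
attractor — a fixed point (cycle of length 1) or a limit cycle — which here
stands for a stable cellular phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ACTIVATION = "activation"
INHIBITION = "inhibition"

SIGN_TOKENS = {"+": ACTIVATION, "-": INHIBITION}
TOKEN_OF_SIGN = {ACTIVATION: "+", INHIBITION: "-"}


class NonConvergenceError(RuntimeError):
    """Raised when no state is revisited within the step budget."""


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: str  # ACTIVATION or INHIBITION

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"unresolved sign {self.sign!r} on edge "
                             f"{self.source}->{self.target}")


class SignedNetwork:
    """Directed signed network over an ordered gene list.

    Internally the regulator structure is held as two boolean matrices
    ``act[t, s]`` / ``inh[t, s]`` so one synchronous update is two
    matrix-vector products.
    """

    def __init__(self, genes: Sequence[str],
                 edges: Iterable[tuple[str, str, str]]) -> None:
        self.genes: list[str] = list(genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        n = len(self.genes)
        self.act = np.zeros((n, n), dtype=bool)
        self.inh = np.zeros((n, n), dtype=bool)
        self.edges: list[SignedEdge] = []
        seen: set[tuple[str, str]] = set()
        for source, target, sign in edges:
            if source not in self.index or target not in self.index:
                raise ValueError(f"edge endpoint not in gene list: "
                                 f"{source}->{target}")
            if (source, target) in seen:
                raise ValueError(f"duplicate edge {source}->{target}")
            seen.add((source, target))
            edge = SignedEdge(source, target, sign)
            self.edges.append(edge)
            s, t = self.index[source], self.index[target]
            (self.act if sign == ACTIVATION else self.inh)[t, s] = True
        # Genes with no regulators are constitutively expressed.
        self.unregulated = ~(self.act.any(axis=1) | self.inh.any(axis=1))
        # integer copies: bool @ bool is a logical OR, but the majority
        # rule needs regulator *counts*
        self._act_i = self.act.astype(np.int16)
        self._inh_i = self.inh.astype(np.int16)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def regulators(self, target: str) -> list[tuple[str, str]]:
        """All (source, sign) pairs regulating ``target``."""
        t = self.index[target]
        out = [(self.genes[s], ACTIVATION) for s in np.flatnonzero(self.act[t])]
        out += [(self.genes[s], INHIBITION) for s in np.flatnonzero(self.inh[t])]
        return out

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(e.source, e.target, e.sign) for e in self.edges}

    def state_from_pattern(self, pattern: Mapping[str, bool]) -> np.ndarray:
        return np.array([bool(pattern[g]) for g in self.genes], dtype=bool)

    def __repr__(self) -> str:
        return (f"SignedNetwork({self.n_genes} genes, "
                f"{len(self.edges)} edges)")


def majority_update(net: SignedNetwork, state: np.ndarray) -> np.ndarray:
    """One synchronous majority-rule update.

    ``next(g)`` is ON iff strictly more ON activators than ON inhibitors;
    ties give OFF; unregulated genes are always ON.
    """
    state = np.asarray(state, dtype=bool).astype(np.int16)
    nxt = net._act_i @ state > net._inh_i @ state
    nxt |= net.unregulated
    return nxt


def batch_majority_update(net: SignedNetwork, states: np.ndarray) -> np.ndarray:
    """Vectorized update of many states at once (rows = states)."""
    counts = np.asarray(states, dtype=np.int16)
    nxt = counts @ net._act_i.T > counts @ net._inh_i.T
    nxt[:, net.unregulated] = True
    return nxt


@dataclass
class Attractor:
    """A synchronous attractor: fixed point (length 1) or limit cycle."""

    states: list[np.ndarray]
    transient: int = 0  # steps taken before entering the cycle

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def __len__(self) -> int:
        return len(self.states)

    def occupancy(self) -> np.ndarray:
        """Mean ON-fraction per gene over the cycle states."""
        return np.mean(np.asarray(self.states, dtype=float), axis=0)

    def to_jsonable(self, genes: Sequence[str]) -> dict:
        return {
            "length": len(self.states),
            "transient": self.transient,
            "states": ["".join("1" if v else "0" for v in s)
                       for s in self.states],
            "genes": list(genes),
        }


def find_attractor(net: SignedNetwork, initial: np.ndarray,
                   max_steps: int | None = None,
                   clamp_mask: np.ndarray | None = None,
                   clamp_values: np.ndarray | None = None) -> Attractor:
    """Iterate synchronous updates from ``initial`` until a state repeats.

    Optionally a set of genes is clamped: after every update (and in the
    initial state) the clamped genes are overridden to fixed values, which
    models a sustained perturbation with dominant effect.

    Raises :class:`NonConvergenceError` if no repeat occurs within
    ``max_steps`` (default ``2**n + 1``, which guarantees termination).
    """
    state = np.array(initial, dtype=bool)
    if clamp_mask is not None:
        state[clamp_mask] = clamp_values[clamp_mask]
    if max_steps is None:
        max_steps = 2 ** net.n_genes + 1
    seen: dict[bytes, int] = {}
    trajectory: list[np.ndarray] = []
    for step in range(max_steps + 1):
        key = state.tobytes()
        if key in seen:
            start = seen[key]
            return Attractor(states=trajectory[start:], transient=start)
        seen[key] = step
        trajectory.append(state)
        state = majority_update(net, state)
        if clamp_mask is not None:
            state[clamp_mask] = clamp_values[clamp_mask]
    raise NonConvergenceError(
        f"no revisited state within {max_steps} steps")


def pattern_agreement(att: Attractor, target: np.ndarray) -> float:
    """Mismatch between an attractor and a target ON/OFF pattern.

    Fixed point: Hamming distance to the target.  Limit cycle: mean Hamming
    distance over the cycle states.
    """
    target = np.asarray(target, dtype=bool)
    dists = [np.count_nonzero(s != target) for s in att.states]
    return float(np.mean(dists))
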