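"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: the dynamics
oracle evaluates the majority rule gene by gene from the raw edge list, and
the cycle oracle enumerates candidate node sequences by permutation.  They
are only feasible on tiny instances, which is the point.
"""

from itertools import combinations, permutations

from diffgrn.boolnet import INHIBITION, SignedNetwork


def slow_update(net: SignedNetwork, state: dict[str, bool]) -> dict[str, bool]:
    """Majority rule computed per gene from the edge list."""
    incoming: dict[str, list[tuple[str, str]]] = {g: [] for g in net.genes}
    for e in net.edges:
        incoming[e.target].append((e.source, e.sign))
    nxt = {}
    for g in net.genes:
        regs = incoming[g]
        if not regs:
            nxt[g] = True
            continue
        act = sum(1 for s, sign in regs if sign != INHIBITION and state[s])
        inh = sum(1 for s, sign in regs if sign == INHIBITION and state[s])
        nxt[g] = act > inh
    return nxt


def transition_table(net: SignedNetwork) -> dict[int, int]:
    """Full 2^n synchronous transition graph, states encoded as bitmasks."""
    n = net.n_genes
    table = {}
    for code in range(2 ** n):
        state = {g: bool(code >> i & 1) for i, g in enumerate(net.genes)}
        nxt = slow_update(net, state)
        table[code] = sum(1 << i for i, g in enumerate(net.genes) if nxt[g])
    return table


def tabulated_attractor(net: SignedNetwork, initial: dict[str, bool],
                        clamp: dict[str, bool] | None = None
                        ) -> list[dict[str, bool]]:
    """Follow the (optionally clamped) transition graph to its cycle."""
    def encode(state: dict[str, bool]) -> int:
        return sum(1 << i for i, g in enumerate(net.genes) if state[g])

    def decode(code: int) -> dict[str, bool]:
        return {g: bool(code >> i & 1) for i, g in enumerate(net.genes)}

    def step(code: int) -> int:
        state = decode(code)
        nxt = slow_update(net, state)
        if clamp:
            nxt.update(clamp)
        return encode(nxt)

    start = dict(initial)
    if clamp:
        start.update(clamp)
    seen: dict[int, int] = {}
    path: list[int] = []
    code = encode(start)
    while code not in seen:
        seen[code] = len(path)
        path.append(code)
        code = step(code)
    return [decode(c) for c in path[seen[code]:]]


def brute_force_simple_cycles(net: SignedNetwork) -> set[tuple[str, ...]]:
    """Every elementary cycle as a canonical node tuple, by permutation.

    A cycle of length L is generated once by fixing its smallest node
    first and permuting the remaining L-1.
    """
    has_edge = {(e.source, e.target) for e in net.edges}
    found: set[tuple[str, ...]] = set()
    genes = sorted(net.genes)
    for L in range(1, len(genes) + 1):
        for subset in combinations(genes, L):
            first = subset[0]  # smallest by construction
            for rest in permutations(subset[1:]):
                cyc = (first,) + rest
                if all((cyc[i], cyc[(i + 1) % L]) in has_edge
                       for i in range(L)):
                    found.add(cyc)
    return found
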