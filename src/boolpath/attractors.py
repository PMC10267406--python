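"""Attractor search by five strategies: exhaustive synchronous enumeration,
SAT-based fixed points and bounded cycles, SCC decomposition, heuristic
sampling, and asynchronous random walks.

An attractor is a terminal set of states: a fixed point (``steady``), a
synchronous cycle (``cycle``), or a terminal strongly connected component
of the asynchronous state-transition graph (``complex``).  Synchronous
cycles are stored in walk order starting from the lexicographically
smallest rotation so deduplication is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from . import sat
from .network import BooleanNetwork, int_to_state, state_to_int
from .dynamics import compile_update, successor_table

__all__ = [
    "Attractor", "exhaustive_sync", "sat_steady_states", "sat_cycles",
    "decomposition_search", "heuristic_search", "async_random_walk",
]

EXHAUSTIVE_CAP_DEFAULT = 24

State = tuple[int, ...]


@dataclass(frozen=True)
class Attractor:
    """A terminal set of states.

    ``states`` is an ordered tuple: the single state for ``steady``, the
    cycle walk (canonical rotation) for ``cycle``, sorted states for
    ``complex``.  ``basin`` counts states attracted to it (synchronous
    exhaustive search only).  ``verified`` is False only for decomposition
    candidates that fail the direct full-network check; ``certified`` is
    False only for async candidates whose closure could not be explored
    within the state cap.
    """
    kind: str                       # 'steady' | 'cycle' | 'complex'
    states: tuple[State, ...]
    basin: int | None = None
    method: str = ""
    seed: int | None = None
    verified: bool = True
    certified: bool = True

    def key(self) -> tuple:
        """Identity for deduplication: kind + canonical state set/cycle."""
        if self.kind == "cycle":
            return (self.kind, self.states)
        return (self.kind, tuple(sorted(self.states)))

    def __len__(self) -> int:
        return len(self.states)


def _canonical_cycle(states: list[State]) -> tuple[State, ...]:
    k = min(range(len(states)), key=lambda i: states[i])
    return tuple(states[k:] + states[:k])


def dedupe(attractors: list[Attractor]) -> list[Attractor]:
    seen: dict[tuple, Attractor] = {}
    for a in attractors:
        seen.setdefault(a.key(), a)
    return sorted(seen.values(), key=lambda a: (a.kind, a.states))


# ---------------------------------------------------------------------------
# exhaustive synchronous search

def exhaustive_sync(network: BooleanNetwork,
                    cap: int = EXHAUSTIVE_CAP_DEFAULT) -> list[Attractor]:
    """Enumerate all synchronous attractors with exact basin sizes.

    Walks the functional graph of the packed successor table; every state
    is assigned to exactly one attractor, so basins partition the 2^n
    state space.
    """
    n = len(network)
    if n > cap:
        raise ValueError(f"{n} nodes exceeds the exhaustive cap ({cap})")
    nxt = successor_table(network)
    total = 1 << n
    label = np.full(total, -1, dtype=np.int64)
    cycles: list[list[int]] = []

    for s0 in range(total):
        if label[s0] >= 0:
            continue
        path = []
        s = s0
        while label[s] == -1:
            label[s] = -2  # on current path
            path.append(s)
            s = int(nxt[s])
        if label[s] == -2:
            # new cycle discovered: extract it from the path tail
            start = path.index(s)
            cyc = path[start:]
            cid = len(cycles)
            cycles.append(cyc)
            for x in cyc:
                label[x] = cid
            tail = path[:start]
        else:
            cid = label[s]
            tail = path
        for x in tail:
            label[x] = cid

    basin_sizes = np.bincount(label, minlength=len(cycles))
    out = []
    for cid, cyc in enumerate(cycles):
        states = [int_to_state(c, n) for c in cyc]
        if len(cyc) == 1:
            out.append(Attractor("steady", (states[0],),
                                 basin=int(basin_sizes[cid]),
                                 method="exhaustive"))
        else:
            out.append(Attractor("cycle", _canonical_cycle(states),
                                 basin=int(basin_sizes[cid]),
                                 method="exhaustive"))
    return sorted(out, key=lambda a: (a.kind, a.states))


# ---------------------------------------------------------------------------
# SAT-based search

def _encode_step(builder: sat.CnfBuilder, network: BooleanNetwork,
                 cur: dict[str, int], nxt: dict[str, int]) -> None:
    """Add clauses forcing nxt = B(cur)."""
    for node in network.nodes:
        lit = builder.add_expr_literal(network.functions[node], cur)
        builder.add_iff(nxt[node], lit)


def sat_steady_states(network: BooleanNetwork,
                      limit: int | None = None) -> list[State]:
    """All synchronous fixed points via satisfiability.

    Encodes x_i ↔ B_i(x) for every node (Tseitin CNF) and enumerates
    models with iterative blocking clauses.
    """
    builder = sat.CnfBuilder()
    env = {node: builder.new_var(node) for node in network.nodes}
    _encode_step(builder, network, env, env)
    project = [env[node] for node in network.nodes]
    states = [tuple(model) for model in
              sat.enumerate_models(builder.n_vars, builder.clauses,
                                   project, limit=limit)]
    return sorted(states)


def sat_cycles(network: BooleanNetwork, L: int,
               limit: int | None = None) -> list[Attractor]:
    """Simple synchronous cycles of exact length L via an unrolled encoding.

    Constrains x^{t+1} = B(x^t) for t < L, closes the loop with
    x^L = x^0, and forces all L states pairwise distinct; each found cycle
    is blocked in all rotations.
    """
    if L < 2:
        raise ValueError("cycle length must be ≥ 2")
    builder = sat.CnfBuilder()
    steps = [{node: builder.new_var(f"{node}@{t}") for node in network.nodes}
             for t in range(L)]
    for t in range(L):
        _encode_step(builder, network, steps[t], steps[(t + 1) % L])
    # pairwise distinctness: some coordinate differs
    for t, u in itertools.combinations(range(L), 2):
        diffs = []
        for node in network.nodes:
            d = builder.new_var()
            a, b = steps[t][node], steps[u][node]
            # d -> (a xor b)
            builder.add([-d, a, b])
            builder.add([-d, -a, -b])
            diffs.append(d)
        builder.add(diffs)

    project = [steps[0][node] for node in network.nodes]
    clauses = list(builder.clauses)
    out: list[Attractor] = []
    cn = compile_update(network)
    while limit is None or len(out) < limit:
        model = sat.solve(builder.n_vars, clauses)
        if model is None:
            break
        start = tuple(1 if model[v - 1] > 0 else 0 for v in project)
        cycle = [start]
        s = cn.step(start)
        while s != start:
            cycle.append(s)
            s = cn.step(s)
        out.append(Attractor("cycle", _canonical_cycle(cycle), method="sat"))
        for rot in cycle:  # block every rotation as a start state
            clauses.append([-v if bit else v
                            for v, bit in zip(project, rot)])
    return dedupe(out)


# ---------------------------------------------------------------------------
# decomposition search

def decomposition_search(network: BooleanNetwork,
                         block_cap: int = 20) -> list[Attractor]:
    """Approximate attractors by strongly-connected-component decomposition.

    The interaction graph is condensed into SCC blocks processed in
    topological order; within each block, attractors are enumerated
    exhaustively under every combination of upstream projections, and the
    per-block fixed patterns are composed into full-network candidates.
    Per block, block-local synchronous attractors (fixed patterns and
    block cycles) are found by walking the block-projected update map with
    upstream nodes frozen at their (time-averaged fixed) candidate values;
    block attractors are composed across blocks over all relative phase
    offsets.  Each candidate carries ``verified=True`` iff it passes a
    direct synchronous check on the full network — composition is an
    approximation and can both manufacture spurious candidates and miss
    attractors that need time-varying upstream context, which is precisely
    the fragility this strategy is known for.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for src, _, tgt in network.interaction_edges():
        g.add_edge(src, tgt)
    # free inputs regulate themselves
    for node in network.inputs:
        g.add_edge(node, node)
    comps = list(nx.strongly_connected_components(g))
    cond = nx.condensation(g, scc=comps)
    order = list(nx.topological_sort(cond))

    cn = compile_update(network)
    # each candidate: node -> periodic value sequence (tuple), all sequences
    # sharing a common period equal to their lcm
    candidates: list[dict[str, tuple[int, ...]]] = [{}]
    for block_id in order:
        members = sorted(cond.nodes[block_id]["members"], key=network.index)
        if len(members) > block_cap:
            raise ValueError(f"SCC block of size {len(members)} exceeds "
                             f"block cap ({block_cap})")
        new_candidates = []
        for cand in candidates:
            upstream = {node: seq[0] for node, seq in cand.items()}
            for cyc in _block_attractors(network, cn, members, upstream):
                period = len(cyc)
                for phase in range(period):
                    merged = dict(cand)
                    for j, node in enumerate(members):
                        merged[node] = tuple(
                            cyc[(t + phase) % period][j]
                            for t in range(period))
                    new_candidates.append(merged)
        candidates = new_candidates

    out = []
    for cand in candidates:
        period = 1
        for seq in cand.values():
            period = period * len(seq) // _gcd(period, len(seq))
        walk = [tuple(cand[node][t % len(cand[node])]
                      for node in network.nodes)
                for t in range(period)]
        # collapse repeats (phases can coincide)
        if walk[0] in walk[1:]:
            walk = walk[:walk[1:].index(walk[0]) + 1]
        verified = all(cn.step(walk[t]) == walk[(t + 1) % len(walk)]
                       for t in range(len(walk)))
        if len(walk) == 1:
            out.append(Attractor("steady", (walk[0],),
                                 method="decomposition", verified=verified))
        else:
            out.append(Attractor("cycle", _canonical_cycle(walk),
                                 method="decomposition", verified=verified))
    return dedupe(out)


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a


def _block_attractors(network: BooleanNetwork, cn, members: list[str],
                      upstream: dict[str, int]):
    """Synchronous attractors of one block with upstream values frozen.

    Yields each attractor as a list of block-bit tuples (length 1 for a
    fixed pattern)."""
    idx = [network.index(m) for m in members]
    n = len(network)
    base = [0] * n
    for node, v in upstream.items():
        base[network.index(node)] = v

    def block_step(bits: tuple[int, ...]) -> tuple[int, ...]:
        state = list(base)
        for j, b in zip(idx, bits):
            state[j] = b
        return tuple(cn.node_next(state, j) for j in idx)

    seen: set[tuple[int, ...]] = set()
    for start_bits in itertools.product((0, 1), repeat=len(members)):
        if start_bits in seen:
            continue
        path = []
        s = start_bits
        while s not in seen and s not in path:
            path.append(s)
            s = block_step(s)
        if s in path:  # new attractor
            cyc = path[path.index(s):]
            k = min(range(len(cyc)), key=lambda i: cyc[i])
            yield cyc[k:] + cyc[:k]
        seen.update(path)


# ---------------------------------------------------------------------------
# heuristic (sampled synchronous) search

def heuristic_search(network: BooleanNetwork, n_starts: int = 100,
                     seed: int = 0) -> list[Attractor]:
    """Synchronous attractors reached from sampled initial states.

    From each start, iterates the synchronous map with Brent's
    cycle-detection algorithm.  Coverage is a lower bound on the true
    attractor set (basins not sampled are missed).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be ≥ 1")
    n = len(network)
    rng = np.random.default_rng(seed)
    cn = compile_update(network)
    out: list[Attractor] = []
    for _ in range(n_starts):
        start = tuple(int(b) for b in rng.integers(0, 2, size=n))
        cycle = _brent_cycle(cn, start)
        if len(cycle) == 1:
            out.append(Attractor("steady", (cycle[0],),
                                 method="heuristic", seed=seed))
        else:
            out.append(Attractor("cycle", _canonical_cycle(cycle),
                                 method="heuristic", seed=seed))
    return dedupe(out)


def _brent_cycle(cn, start: State) -> list[State]:
    """Brent's algorithm: return the cycle reached from ``start``."""
    power = lam = 1
    tortoise = start
    hare = cn.step(start)
    while tortoise != hare:
        if power == lam:
            tortoise = hare
            power *= 2
            lam = 0
        hare = cn.step(hare)
        lam += 1
    # find a state on the cycle: advance lam steps from start
    s = start
    for _ in range(lam):
        s = cn.step(s)
    mu = start
    while mu != s:
        mu = cn.step(mu)
        s = cn.step(s)
    cycle = [mu]
    s = cn.step(mu)
    while s != mu:
        cycle.append(s)
        s = cn.step(s)
    return cycle


# ---------------------------------------------------------------------------
# asynchronous random-walk search

def async_random_walk(network: BooleanNetwork, n_runs: int = 100,
                      max_steps: int = 1000, seed: int = 0,
                      state_cap: int = 4096) -> list[Attractor]:
    """Steady states and complex attractors from random asynchronous walks.

    Each run walks with uniform choice among eligible node updates.  A
    state with no eligible update is a steady state.  Otherwise the
    walk's final state seeds a bounded forward exploration; the terminal
    SCCs of the explored region are reported as complex attractors and
    certified closed (every asynchronous successor of every member stays
    inside).  If exploration exceeds ``state_cap`` states the tail is
    reported as an uncertified candidate.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be ≥ 1")
    n = len(network)
    rng = np.random.default_rng(seed)
    cn = compile_update(network)
    out: list[Attractor] = []
    for _ in range(n_runs):
        state = [int(b) for b in rng.integers(0, 2, size=n)]
        steady = None
        for _ in range(max_steps):
            eligible = [i for i in range(n)
                        if cn.node_next(state, i) != state[i]]
            if not eligible:
                steady = tuple(state)
                break
            i = eligible[rng.integers(0, len(eligible))]
            state[i] = 1 - state[i]
        if steady is not None:
            out.append(Attractor("steady", (steady,),
                                 method="async", seed=seed))
            continue
        out.extend(_terminal_sccs_from(cn, tuple(state), state_cap, seed))
    return dedupe(out)


def _terminal_sccs_from(cn, tail: State, state_cap: int,
                        seed: int) -> list[Attractor]:
    """Terminal SCCs of the async STG restricted to states reachable from
    ``tail`` (bounded exploration)."""
    n = cn.n
    g = nx.DiGraph()
    seen = {tail}
    stack = [tail]
    g.add_node(tail)
    while stack:
        if len(seen) > state_cap:
            return [Attractor("complex", (tail,), method="async", seed=seed,
                              certified=False)]
        s = stack.pop()
        for i in range(n):
            v = cn.node_next(s, i)
            if v != s[i]:
                t = s[:i] + (v,) + s[i + 1:]
                g.add_edge(s, t)
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
    out = []
    for comp in nx.strongly_connected_components(g):
        closed = all(t in comp for u in comp for t in g.successors(u))
        if not closed:
            continue
        if len(comp) == 1:
            s = next(iter(comp))
            if g.out_degree(s) == 0:
                out.append(Attractor("steady", (s,), method="async",
                                     seed=seed))
        else:
            out.append(Attractor("complex", tuple(sorted(comp)),
                                 method="async", seed=seed))
    return out
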