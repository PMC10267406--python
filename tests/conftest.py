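"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's production code paths:
centralities are recomputed by explicit BFS path enumeration, synchronous
attractors by walking ``sync_step`` state by state, and the stochastic
engine is checked against the exact chain's matrix exponential.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from boolpath import GeneratorSpec, random_network, sync_step
from boolpath.network import BooleanNetwork, int_to_state, state_to_int


def make_random_networks(count: int, max_n: int, max_k: float = 3.0,
                         seed0: int = 100) -> list[BooleanNetwork]:
    """A seeded ensemble of N-K-p networks with n ≤ max_n."""
    rng = np.random.default_rng(seed0)
    nets = []
    for i in range(count):
        n = int(rng.integers(3, max_n + 1))
        k = float(rng.uniform(1.0, min(max_k, n - 1)))
        nets.append(random_network(GeneratorSpec(
            n=n, k=k, p=float(rng.uniform(0.3, 0.7)), seed=seed0 + i)))
    return nets


# ---------------------------------------------------------------------------
# centrality oracle: explicit shortest-path enumeration

def enumerate_shortest_paths(adj: dict[str, list[str]], s: str, t: str
                             ) -> list[tuple[str, ...]]:
    """All shortest s→t paths by BFS distances + DFS over tight edges."""
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj.get(u, []):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    if t not in dist:
        return []
    paths: list[tuple[str, ...]] = []

    def walk(u: str, acc: list[str]) -> None:
        if u == t:
            paths.append(tuple(acc))
            return
        for w in adj.get(u, []):
            if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                walk(w, acc + [w])

    walk(s, [s])
    return paths


def oracle_centralities(nodes: list[str], adj: dict[str, list[str]]
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """(betweenness, stress) by brute-force path enumeration."""
    cb = {v: 0.0 for v in nodes}
    cs = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            cb[v] += through / len(paths)
            cs[v] += through
    return cb, cs


# ---------------------------------------------------------------------------
# synchronous attractor oracle: stepwise walking

def oracle_sync_attractors(net: BooleanNetwork
                           ) -> dict[frozenset[tuple[int, ...]], int]:
    """Map attractor state-set -> basin size, by walking sync_step from
    every state with memoization-free path chasing."""
    n = len(net)
    reached: dict[int, frozenset] = {}
    basins: dict[frozenset, int] = {}
    for code in range(1 << n):
        path = []
        s = code
        while s not in reached and s not in path:
            path.append(s)
            s = state_to_int(sync_step(net, int_to_state(s, n)))
        if s in reached:
            att = reached[s]
        else:
            cyc = path[path.index(s):]
            att = frozenset(int_to_state(c, n) for c in cyc)
        for x in path:
            reached[x] = att
        basins[att] = basins.get(att, 0) + 1
    return basins


def oracle_async_terminal_sccs(net: BooleanNetwork) -> set[frozenset]:
    """Terminal SCCs of the full asynchronous STG, via Tarjan on the
    explicitly built graph (n small)."""
    import networkx as nx

    from boolpath import async_step

    n = len(net)
    g = nx.DiGraph()
    for code in range(1 << n):
        state = int_to_state(code, n)
        g.add_node(state)
        for node in net.nodes:
            t = async_step(net, state, node)
            if t != state:
                g.add_edge(state, t)
    out = set()
    for comp in nx.strongly_connected_components(g):
        if all(t in comp for u in comp for t in g.successors(u)):
            out.add(frozenset(comp))
    return out


# ---------------------------------------------------------------------------
# exact CTMC oracle

def exact_ctmc_on_probabilities(net: BooleanNetwork, p0: np.ndarray,
                                times: np.ndarray,
                                up: float = 1.0, down: float = 1.0
                                ) -> np.ndarray:
    """Exact per-node ON probabilities: build the full transition-rate
    matrix and propagate with the matrix exponential."""
    from scipy.linalg import expm

    n = len(net)
    size = 1 << n
    q = np.zeros((size, size))
    for code in range(size):
        state = int_to_state(code, n)
        nxt = sync_step(net, state)
        for i in range(n):
            if nxt[i] != state[i]:
                rate = up if nxt[i] == 1 else down
                q[code, code ^ (1 << i)] += rate
        q[code, code] = -q[code].sum()
    out = np.zeros((len(times), n))
    for r, t in enumerate(times):
        pt = p0 @ expm(q * t)
        for i in range(n):
            on = [c for c in range(size) if (c >> i) & 1]
            out[r, i] = pt[on].sum()
    return out


@pytest.fixture
def toggle():
    from boolpath import motif
    return motif("toggle")


@pytest.fixture
def repressilator():
    from boolpath import motif
    return motif("repressilator")
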