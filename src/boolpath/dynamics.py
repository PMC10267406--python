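"""Boolean dynamics: synchronous / asynchronous stepping, state-transition
graphs, and continuous-time stochastic (Gillespie) simulation.

States are 0/1 tuples in network node order; state-space structures use
the packed integer encoding (node i = bit i).

The stochastic engine follows the random-walk semantics of continuous-time
Markov Boolean simulation: at any state the *eligible* nodes are those
whose function disagrees with their current value; each carries a flip
propensity (the node's up-rate when flipping 0→1, down-rate when 1→0);
the waiting time to the next jump is exponential with the summed
propensity and the flipped node is chosen proportionally.  A state with no
eligible node is absorbing (an asynchronous steady state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx

from .network import BooleanNetwork, int_to_state, state_to_int

__all__ = [
    "sync_step", "async_step", "successor_table", "build_stg",
    "StateTransitionGraph", "CtmcConfig", "TrajectoryEstimate",
    "simulate_ctmc", "compile_update",
]

STG_CAP_DEFAULT = 20


# ---------------------------------------------------------------------------
# compiled update functions

class CompiledNetwork:
    """Per-node regulator lists + truth tables for fast repeated stepping."""

    def __init__(self, network: BooleanNetwork):
        self.network = network
        self.n = len(network)
        self.reg_idx: list[np.ndarray] = []
        self.tables: list[np.ndarray] = []
        for node in network.nodes:
            regs, outs = network.truth_table(node)
            self.reg_idx.append(
                np.array([network.index(r) for r in regs], dtype=np.int64))
            self.tables.append(np.array(outs, dtype=np.uint8))

    def node_next(self, state: Sequence[int], i: int) -> int:
        regs = self.reg_idx[i]
        key = 0
        for b, j in enumerate(regs):
            if state[j]:
                key |= 1 << b
        return int(self.tables[i][key])

    def step(self, state: Sequence[int]) -> tuple[int, ...]:
        return tuple(self.node_next(state, i) for i in range(self.n))


def compile_update(network: BooleanNetwork) -> CompiledNetwork:
    """Precompute truth tables; worthwhile for long simulations."""
    return CompiledNetwork(network)


# ---------------------------------------------------------------------------
# stepping

def sync_step(network: BooleanNetwork, state: Sequence[int]) -> tuple[int, ...]:
    """Simultaneous update of every node: s'_i = B_i(s)."""
    env = {n: state[i] for i, n in enumerate(network.nodes)}
    return tuple(network.functions[n].evaluate(env) for n in network.nodes)


def async_step(network: BooleanNetwork, state: Sequence[int],
               node: str) -> tuple[int, ...]:
    """Recompute one chosen node; all other coordinates unchanged."""
    if node not in network.functions:
        raise KeyError(f"unknown node {node!r}")
    env = {n: state[i] for i, n in enumerate(network.nodes)}
    new = list(state)
    new[network.index(node)] = network.functions[node].evaluate(env)
    return tuple(new)


def successor_table(network: BooleanNetwork,
                    chunk_bits: int = 20) -> np.ndarray:
    """Packed synchronous successor of every state: nxt[s] = int(sync_step(s)).

    Vectorized over chunks of the state space to bound memory.
    """
    n = len(network)
    total = 1 << n
    nxt = np.empty(total, dtype=np.uint32 if n <= 32 else np.uint64)
    step = min(total, 1 << chunk_bits)
    for start in range(0, total, step):
        codes = np.arange(start, min(start + step, total), dtype=np.int64)
        vals = network.node_values_over_states(codes)  # (n, chunk) bool
        packed = np.zeros(len(codes), dtype=np.int64)
        for i in range(n):
            packed |= vals[i].astype(np.int64) << i
        nxt[start:start + len(codes)] = packed
    return nxt


# ---------------------------------------------------------------------------
# state-transition graphs

@dataclass
class StateTransitionGraph:
    """All states (packed ints) and allowed transitions under a scheme."""
    scheme: str                      # 'synchronous' | 'asynchronous'
    n_nodes: int
    graph: nx.DiGraph                # nodes: packed states

    def states(self) -> list[int]:
        return list(self.graph.nodes)

    def as_tuples(self) -> list[tuple[int, ...]]:
        return [int_to_state(s, self.n_nodes) for s in self.graph.nodes]


def build_stg(network: BooleanNetwork, scheme: str = "synchronous",
              initial_states: Iterable[Sequence[int]] | None = None,
              cap: int = STG_CAP_DEFAULT) -> StateTransitionGraph:
    """Build the full (n ≤ cap) or reachable state-transition graph.

    Synchronous: one edge s → sync_step(s) per state (self-loops kept so
    fixed points are visible as loops).  Asynchronous: one edge per node
    whose update changes the state; self-loops omitted, so steady states
    are exactly the sink states.
    """
    if scheme not in ("synchronous", "asynchronous"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n = len(network)
    g = nx.DiGraph()
    if initial_states is None:
        if n > cap:
            raise ValueError(
                f"{n} nodes exceeds the full-enumeration cap ({cap}); "
                "pass initial_states for a reachable-set build")
        seeds = range(1 << n)
        full = True
    else:
        seeds = [state_to_int(s) for s in initial_states]
        full = False

    cn = compile_update(network)
    seen: set[int] = set()
    stack = list(seeds)
    for s in stack:
        g.add_node(s)
    while stack:
        code = stack.pop()
        if code in seen:
            continue
        seen.add(code)
        state = int_to_state(code, n)
        succs = _successors(cn, state, code, scheme)
        for t in succs:
            g.add_edge(code, t)
            if not full and t not in seen:
                stack.append(t)
    return StateTransitionGraph(scheme, n, g)


def _successors(cn: CompiledNetwork, state: tuple[int, ...], code: int,
                scheme: str) -> list[int]:
    if scheme == "synchronous":
        return [state_to_int(cn.step(state))]
    out = []
    for i in range(cn.n):
        v = cn.node_next(state, i)
        if v != state[i]:
            out.append(code ^ (1 << i))
    return out


def async_successors(network: BooleanNetwork,
                     state: Sequence[int]) -> list[tuple[int, ...]]:
    """States reachable by flipping one node whose update disagrees."""
    cn = compile_update(network)
    code = state_to_int(state)
    return [int_to_state(c, len(network))
            for c in _successors(cn, tuple(state), code, "asynchronous")]


# ---------------------------------------------------------------------------
# continuous-time stochastic simulation

@dataclass
class CtmcConfig:
    """Configuration for Gillespie-style stochastic Boolean simulation.

    Attributes
    ----------
    up_rates, down_rates
        Per-node transition rates (1/time) for 0→1 and 1→0 flips; nodes
        not listed default to 1.0.
    n_trajectories
        Monte-Carlo sample size.
    max_time
        Simulated time horizon.
    time_bins
        Number of equal bins of [0, max_time] on which occupancies are
        estimated.
    seed
        RNG seed; the full output is reproducible from it.
    initial_state
        Either an explicit 0/1 vector, or a mapping node → ON-probability
        (unspecified nodes default to 0.5), or None for all-nodes 0.5.
    """
    up_rates: Mapping[str, float] = field(default_factory=dict)
    down_rates: Mapping[str, float] = field(default_factory=dict)
    n_trajectories: int = 1000
    max_time: float = 10.0
    time_bins: int = 50
    seed: int = 0
    initial_state: Sequence[int] | Mapping[str, float] | None = None

    def validate(self, network: BooleanNetwork) -> None:
        for rates in (self.up_rates, self.down_rates):
            for node, r in rates.items():
                if node not in network.functions:
                    raise KeyError(f"unknown node {node!r} in rates")
                if r <= 0:
                    raise ValueError(f"rate for {node!r} must be > 0")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be ≥ 1")
        if self.time_bins < 1:
            raise ValueError("time_bins must be ≥ 1")
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if isinstance(self.initial_state, Mapping):
            for node in self.initial_state:
                if node not in network.functions:
                    raise KeyError(f"unknown node {node!r} in initial_state")
        elif self.initial_state is not None:
            if len(self.initial_state) != len(network):
                raise ValueError("initial_state length mismatch")


@dataclass
class TrajectoryEstimate:
    """Monte-Carlo estimates from stochastic simulation."""
    nodes: list[str]
    time_grid: np.ndarray                 # bin right edges, shape (bins,)
    on_probability: np.ndarray            # (bins, n_nodes)
    on_stderr: np.ndarray                 # (bins, n_nodes)
    final_patterns: dict[tuple[int, ...], float]  # state -> occupancy at T
    n_trajectories: int
    seed: int

    def node_series(self, node: str) -> np.ndarray:
        return self.on_probability[:, self.nodes.index(node)]

    def node_stderr(self, node: str) -> np.ndarray:
        return self.on_stderr[:, self.nodes.index(node)]

    def final_probability(self, node: str) -> float:
        return float(self.on_probability[-1, self.nodes.index(node)])

    def final_stderr(self, node: str) -> float:
        return float(self.on_stderr[-1, self.nodes.index(node)])


def simulate_ctmc(network: BooleanNetwork,
                  config: CtmcConfig) -> TrajectoryEstimate:
    """Monte-Carlo random-walk simulation of the Boolean network as a
    continuous-time Markov chain.

    Each trajectory starts from a draw of the initial condition and jumps
    between states by flipping single eligible nodes (Gillespie sampling);
    it ends at ``max_time`` or in an absorbing steady state.  Per-node
    ON-probabilities are recorded on a uniform time grid (value at each
    bin's right edge), and occupancy of distinct final states at
    ``max_time`` is tallied.
    """
    config.validate(network)
    cn = compile_update(network)
    n = len(network)
    rng = np.random.default_rng(config.seed)
    up = np.array([config.up_rates.get(node, 1.0) for node in network.nodes])
    down = np.array([config.down_rates.get(node, 1.0) for node in network.nodes])

    bins = config.time_bins
    grid = np.linspace(config.max_time / bins, config.max_time, bins)
    on_counts = np.zeros((bins, n), dtype=np.int64)
    final_counts: dict[tuple[int, ...], int] = {}

    init_p = _initial_probabilities(network, config)
    for _ in range(config.n_trajectories):
        if init_p is None:
            state = list(config.initial_state)  # type: ignore[arg-type]
        else:
            state = list((rng.random(n) < init_p).astype(int))
        t = 0.0
        bin_ptr = 0
        while True:
            eligible = [i for i in range(n) if cn.node_next(state, i) != state[i]]
            if not eligible:
                break
            props = np.array([down[i] if state[i] else up[i] for i in eligible])
            total = props.sum()
            dt = rng.exponential(1.0 / total)
            if t + dt > config.max_time:
                break
            # record the held state over bins passed before this jump
            while bin_ptr < bins and grid[bin_ptr] <= t + dt:
                on_counts[bin_ptr] += state
                bin_ptr += 1
            t += dt
            i = eligible[rng.choice(len(eligible), p=props / total)]
            state[i] = 1 - state[i]
        while bin_ptr < bins:
            on_counts[bin_ptr] += state
            bin_ptr += 1
        key = tuple(state)
        final_counts[key] = final_counts.get(key, 0) + 1

    m = config.n_trajectories
    p = on_counts / m
    stderr = np.sqrt(p * (1 - p) / m)
    patterns = {k: v / m for k, v in sorted(final_counts.items(),
                                            key=lambda kv: -kv[1])}
    return TrajectoryEstimate(list(network.nodes), grid, p, stderr,
                              patterns, m, config.seed)


def _initial_probabilities(network: BooleanNetwork,
                           config: CtmcConfig) -> np.ndarray | None:
    init = config.initial_state
    if init is None:
        return np.full(len(network), 0.5)
    if isinstance(init, Mapping):
        return np.array([float(init.get(node, 0.5)) for node in network.nodes])
    return None  # explicit fixed state
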