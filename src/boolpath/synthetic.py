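"""Seeded synthetic Boolean networks and pathway-like fixtures.

Three generators:

* :func:`random_network` — the classic N-K-p random Boolean ensemble
  (regulators sampled without replacement, truth-table entries ON with
  bias p).
* :func:`motif` — small fixed networks with known attractor structure
  (toggle switch, repressilator, an inhibited kinase cascade, an
  input–cascade–phenotype network with "autophagy"/"neuron_death" sinks).
* :func:`pathway_like` — layered input → signaling → phenotype topologies
  at the node/edge scales typical of curated disease-map pathway models
  (small ≈ 65 nodes / 86 edges, medium ≈ 167/196, large ≈ 391/436), with
  feedback edges at the medium/large scales.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expr import Const, Expr, Not, Var, and_all, or_all
from .network import BooleanNetwork

__all__ = ["GeneratorSpec", "random_network", "motif", "pathway_like",
           "MOTIFS", "PATHWAY_SCALES"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the N-K-p random ensemble.

    n: node count; k: mean in-degree (per-node in-degree ~ Poisson(k),
    truncated to [0, n-1]); p: probability a truth-table entry is 1;
    input_fraction: fraction of nodes made free inputs; n_sinks: trailing
    phenotype nodes excluded from regulator candidacy (out-degree 0);
    n_feedback: reciprocal regulator pairs forced into the wiring.
    """
    n: int
    k: float = 2.0
    p: float = 0.5
    input_fraction: float = 0.0
    n_sinks: int = 0
    n_feedback: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be ≥ 1")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.k < 0:
            raise ValueError("k must be ≥ 0")
        if self.k >= self.n:
            raise ValueError("mean in-degree k must be < n")
        if not 0 <= self.input_fraction <= 1:
            raise ValueError("input_fraction must be in [0, 1]")
        if self.n_sinks + round(self.input_fraction * self.n) > self.n:
            raise ValueError("inputs + sinks exceed node count")


def _table_to_expr(regs: list[str], table: np.ndarray) -> Expr:
    """Truth table → DNF expression (OR of AND minterms)."""
    if table.all():
        return Const(1)
    if not table.any():
        return Const(0)
    minterms = []
    for key in np.flatnonzero(table):
        lits: list[Expr] = []
        for b, reg in enumerate(regs):
            v = Var(reg)
            lits.append(v if (int(key) >> b) & 1 else Not(v))
        minterms.append(and_all(lits))
    return or_all(minterms)


def random_network(spec: GeneratorSpec) -> BooleanNetwork:
    """Sample one network from the N-K-p ensemble described by ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = [f"v{i:03d}" for i in range(spec.n)]
    n_inputs = round(spec.input_fraction * spec.n)
    inputs = set(names[:n_inputs])
    sinks = set(names[spec.n - spec.n_sinks:]) - inputs

    candidates = [x for x in names if x not in sinks]
    regulators: dict[str, list[str]] = {}
    for name in names:
        if name in inputs:
            regulators[name] = []
            continue
        pool = [c for c in candidates if c != name] or [name]
        k = min(len(pool), int(rng.poisson(spec.k)))
        chosen = rng.choice(len(pool), size=k, replace=False) if k else []
        regulators[name] = sorted(pool[int(i)] for i in chosen)

    # force reciprocal pairs for feedback-loop targets
    pair_pool = [x for x in candidates if x not in inputs]
    made = 0
    for a, b in zip(pair_pool[::2], pair_pool[1::2]):
        if made >= spec.n_feedback:
            break
        for u, v in ((a, b), (b, a)):
            if v not in regulators[u]:
                regulators[u] = sorted(regulators[u] + [v])
        made += 1

    functions: dict[str, Expr] = {}
    for name in names:
        if name in inputs:
            functions[name] = Var(name)
            continue
        regs = regulators[name]
        if not regs:
            functions[name] = Const(int(rng.random() < spec.p))
            continue
        # redraw constant tables (bounded) so sampled regulators stay
        # effective; extreme biases fall back to the constant
        for _ in range(64):
            table = rng.random(1 << len(regs)) < spec.p
            if table.any() and not table.all():
                break
        functions[name] = _table_to_expr(regs, table)
    return BooleanNetwork(functions, {"name": f"nkp_n{spec.n}_s{spec.seed}"})


# ---------------------------------------------------------------------------
# motifs

def _rules(lines: dict[str, str]) -> BooleanNetwork:
    from .model_io import read_rules
    return read_rules("\n".join(f"{k}, {v}" for k, v in lines.items()))


def _toggle() -> BooleanNetwork:
    # mutual repression: two steady states (1,0) and (0,1); the sync
    # scheme adds the {(0,0),(1,1)} two-cycle
    return _rules({"A": "!B", "B": "!A"})


def _repressilator() -> BooleanNetwork:
    # 3-node negative feedback loop; one complex async attractor (6 states)
    return _rules({"A": "!C", "B": "!A", "C": "!B"})


def _inhibited_cascade() -> BooleanNetwork:
    # tau-phosphorylation fragment: kinase output requires the activating
    # complex present and the counteracting isomerase absent
    return _rules({
        "CDK5_p25": "CDK5_p25",
        "PIN1": "PIN1",
        "MAPTP": "CDK5_p25 & !PIN1",
    })


def _cascade_phenotype() -> BooleanNetwork:
    # two inputs driving a three-step cascade onto two phenotype sinks;
    # stress promotes neuron death and suppresses the protective arm
    return _rules({
        "growth_factor": "growth_factor",
        "stress": "stress",
        "kinase1": "growth_factor",
        "kinase2": "kinase1 & !stress",
        "tf": "kinase2 | stress",
        "autophagy": "tf & !stress",
        "neuron_death": "stress & !kinase2",
    })


MOTIFS = {
    "toggle": _toggle,
    "repressilator": _repressilator,
    "inhibited_cascade": _inhibited_cascade,
    "cascade_phenotype": _cascade_phenotype,
}


def motif(name: str) -> BooleanNetwork:
    """A fixed, documented small network with known attractor structure."""
    if name not in MOTIFS:
        raise KeyError(f"unknown motif {name!r}; available: "
                       f"{sorted(MOTIFS)}")
    net = MOTIFS[name]()
    net.metadata["name"] = name
    return net


# ---------------------------------------------------------------------------
# pathway-like fixtures

PATHWAY_SCALES = {
    # scale: (nodes, edges, inputs, sinks, feedback edges)
    "small": (65, 86, 6, 3, 0),
    "medium": (167, 196, 10, 4, 3),
    "large": (391, 436, 16, 6, 6),
}


def pathway_like(scale: str = "small", seed: int = 0) -> BooleanNetwork:
    """A layered signaling-pathway-like Boolean network.

    Nodes split into free inputs, interior signaling nodes, and phenotype
    sinks ("autophagy"-style read-outs with no outgoing edges).  Every
    non-input node keeps at least one regulator among earlier nodes, so
    all phenotypes are reachable from some input.  Interaction signs are
    sampled (activation 3:1 over inhibition) and each node's function is
    the OR of its activators vetoed by any inhibitor.  Medium and large
    scales add feedback edges from interior nodes back to earlier ones.
    """
    if scale not in PATHWAY_SCALES:
        raise KeyError(f"unknown scale {scale!r}; available: "
                       f"{sorted(PATHWAY_SCALES)}")
    n_nodes, n_edges, n_inputs, n_sinks, n_feedback = PATHWAY_SCALES[scale]
    rng = np.random.default_rng(seed)

    names = [f"in{i:02d}" for i in range(n_inputs)]
    names += [f"sig{i:03d}" for i in range(n_nodes - n_inputs - n_sinks)]
    names += [f"phen{i}" for i in range(n_sinks)]
    pos = {x: i for i, x in enumerate(names)}
    interior_hi = n_nodes - n_sinks  # regulator candidates: indices < this

    edges: set[tuple[str, str]] = set()
    parent = {}
    # backbone: one upstream regulator per non-input node
    for i in range(n_inputs, n_nodes):
        j = int(rng.integers(0, min(i, interior_hi)))
        edges.add((names[j], names[i]))
        parent[i] = j
    # feedback edges close a backbone ancestor chain into a cycle
    fb_added = 0
    attempts = 0
    while fb_added < n_feedback and attempts < 1000:
        attempts += 1
        i = int(rng.integers(n_inputs + 1, interior_hi))
        ancestors = []
        j = parent[i]
        while j >= n_inputs:
            ancestors.append(j)
            j = parent[j]
        if not ancestors:
            continue
        j = ancestors[int(rng.integers(0, len(ancestors)))]
        e = (names[i], names[j])
        if e not in edges:
            edges.add(e)
            fb_added += 1
    # fill the remaining budget with forward edges
    while len(edges) < n_edges:
        t = int(rng.integers(n_inputs, n_nodes))
        s = int(rng.integers(0, min(pos[names[t]], interior_hi)))
        e = (names[s], names[t])
        if e not in edges:
            edges.add(e)

    incoming: dict[str, list[tuple[str, int]]] = {x: [] for x in names}
    for s, t in sorted(edges):
        sign = 1 if rng.random() < 0.75 else -1
        incoming[t].append((s, sign))

    functions: dict[str, Expr] = {}
    for x in names:
        regs = incoming[x]
        if not regs:
            functions[x] = Var(x)  # free input
            continue
        activators = [Var(s) for s, sign in regs if sign > 0]
        inhibitors = [Var(s) for s, sign in regs if sign < 0]
        if activators and inhibitors:
            functions[x] = or_all(activators) & ~or_all(inhibitors)
        elif activators:
            functions[x] = or_all(activators)
        else:
            functions[x] = ~or_all(inhibitors)
    return BooleanNetwork(functions,
                          {"name": f"pathway_{scale}_s{seed}"})
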