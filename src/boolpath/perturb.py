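"""Perturbation sensitivity: knockouts/overexpressions, attractor-level
distances, and centrality × sensitivity target prioritization.

A perturbation clamps one node's function to a constant (knockout = 0,
overexpression = 1).  Sensitivity compares the attractor landscapes
before and after: both landscapes are collapsed to the UNION of their
attractor states, projected onto all coordinates except the perturbed
node (whose value the clamp fixes by fiat), and compared with

* the similarity score  d_sim = |A∩B| / |A∪B|   (Jaccard; 1 = unchanged), and
* the identity distance d_id  = 1 − |A∩B| / |A_unpert|  (0 = unchanged).

The headline scalar sensitivity is d_id.  ``1 − d_sim`` is also reported
as ``dissimilarity`` since the Jaccard form, though conventionally called
a distance in this setting, is a similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .expr import Const
from .network import BooleanNetwork
from .attractors import Attractor, async_random_walk, sat_steady_states

__all__ = [
    "Perturbation", "clamp", "similarity_distance", "identity_distance",
    "attractor_state_union", "knockout_sensitivity", "sensitivity_report",
    "prioritize_targets",
]

State = tuple[int, ...]

MODES = {"knockout": 0, "overexpression": 1}


@dataclass(frozen=True)
class Perturbation:
    node: str
    mode: str  # 'knockout' | 'overexpression'

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def value(self) -> int:
        return MODES[self.mode]


def clamp(network: BooleanNetwork, perturbation: Perturbation) -> BooleanNetwork:
    """Replace the perturbed node's function by the clamp constant."""
    if perturbation.node not in network.functions:
        raise KeyError(f"unknown node {perturbation.node!r}")
    return network.copy({perturbation.node: Const(perturbation.value)})


def similarity_distance(a_unpert: set[State], a_pert: set[State]) -> float:
    """Jaccard similarity of two attractor-state sets; two empty sets
    compare as identical (1)."""
    if not a_unpert and not a_pert:
        return 1.0
    return len(a_unpert & a_pert) / len(a_unpert | a_pert)


def identity_distance(a_unpert: set[State], a_pert: set[State]) -> float:
    """Fraction of the unperturbed attractor states lost after perturbation."""
    if not a_unpert:
        raise ValueError("unperturbed attractor-state set is empty")
    return 1.0 - len(a_unpert & a_pert) / len(a_unpert)


def default_search(network: BooleanNetwork, seed: int = 0) -> list[Attractor]:
    """Default attractor landscape: SAT fixed points plus asynchronous
    random-walk complex attractors."""
    out = [Attractor("steady", (s,), method="sat")
           for s in sat_steady_states(network)]
    out += [a for a in async_random_walk(network, n_runs=50, seed=seed)
            if a.kind == "complex"]
    return out


def attractor_state_union(attractors: Iterable[Attractor],
                          drop_index: int | None = None) -> set[State]:
    """Union of all attractor states, optionally projecting out one
    coordinate."""
    out: set[State] = set()
    for a in attractors:
        for s in a.states:
            if drop_index is not None:
                s = s[:drop_index] + s[drop_index + 1:]
            out.add(s)
    return out


def knockout_sensitivity(
        network: BooleanNetwork, node: str, mode: str = "knockout",
        search: Callable[[BooleanNetwork], list[Attractor]] | None = None,
        unperturbed: list[Attractor] | None = None,
        ) -> dict[str, float]:
    """Sensitivity of the attractor landscape to clamping one node.

    Returns a report row with ``d_sim``, ``d_id``, ``dissimilarity``,
    attractor counts, and the headline scalar ``sensitivity`` (= d_id).
    ``unperturbed`` may carry a precomputed baseline landscape to avoid
    recomputing it per node.
    """
    if search is None:
        search = default_search
    if unperturbed is None:
        unperturbed = search(network)
    perturbation = Perturbation(node, mode)
    perturbed = search(clamp(network, perturbation))
    drop = network.index(node)
    a = attractor_state_union(unperturbed, drop_index=drop)
    b = attractor_state_union(perturbed, drop_index=drop)
    d_sim = similarity_distance(a, b)
    d_id = identity_distance(a, b)
    return {
        "node": node,
        "mode": mode,
        "d_sim": d_sim,
        "dissimilarity": 1.0 - d_sim,
        "d_id": d_id,
        "sensitivity": d_id,
        "n_attractors_before": len(unperturbed),
        "n_attractors_after": len(perturbed),
    }


def sensitivity_report(
        network: BooleanNetwork,
        nodes: Sequence[str] | None = None,
        modes: Sequence[str] = ("knockout", "overexpression"),
        search: Callable[[BooleanNetwork], list[Attractor]] | None = None,
        seed: int = 0) -> pd.DataFrame:
    """Sensitivity rows for every (node, mode) pair.

    The unperturbed landscape is computed once and shared across rows.
    """
    if search is None:
        search = lambda net: default_search(net, seed=seed)
    if nodes is None:
        nodes = network.nodes
    baseline = search(network)
    rows = [knockout_sensitivity(network, node, mode, search=search,
                                 unperturbed=baseline)
            for node in nodes for mode in modes]
    df = pd.DataFrame(rows)
    df["seed"] = seed
    return df


def prioritize_targets(centrality: pd.DataFrame, sensitivity: pd.DataFrame,
                       q: float = 0.25) -> pd.DataFrame:
    """Rank nodes by combined (min–max normalized) betweenness and d_id.

    ``sensitivity`` rows are reduced to one scalar per node (max d_id over
    modes).  The result is sorted by descending priority; the ``in_top_q``
    column marks nodes in the intersection of the top-q sets of both
    criteria separately.
    """
    if centrality.empty or sensitivity.empty:
        raise ValueError("empty input table")
    sens = (sensitivity.groupby("node")["d_id"].max()
            .rename("sensitivity").reset_index())
    df = centrality[["node", "betweenness"]].merge(sens, on="node",
                                                   how="inner")
    if df.empty:
        raise ValueError("centrality and sensitivity tables share no nodes")

    def _minmax(col: pd.Series) -> pd.Series:
        lo, hi = col.min(), col.max()
        if hi == lo:
            return pd.Series(np.zeros(len(col)), index=col.index)
        return (col - lo) / (hi - lo)

    df["betweenness_norm"] = _minmax(df["betweenness"])
    df["sensitivity_norm"] = _minmax(df["sensitivity"])
    df["priority"] = (df["betweenness_norm"] + df["sensitivity_norm"]) / 2

    def _top(col: str) -> set[str]:
        thresh = df[col].quantile(1 - q)
        return set(df.loc[df[col] >= thresh, "node"])

    common = _top("betweenness") & _top("sensitivity")
    df["in_top_q"] = df["node"].isin(common)
    df = df.sort_values(["priority", "node"],
                        ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
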