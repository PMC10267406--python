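"""Structural statistics used to rank nodes of an interaction graph.

All measures are computed on the directed activity-flow graph (regulator →
target), unweighted, with unnormalized centralities: betweenness

    C_B(v) = Σ_{s≠v≠t} σ(s,t|v) / σ(s,t)

over ordered pairs with σ(s,t) > 0, and stress

    C_S(v) = Σ_{s≠v≠t} g_st(v)

where g_st(v) counts the shortest s→t paths through v.  Endpoints are
excluded.  An ``undirected=True`` flag symmetrizes the graph first.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

__all__ = [
    "build_graph", "betweenness", "stress", "feedback_loops",
    "centrality_table", "top_quantile",
]


def build_graph(edges: list[tuple[str, str, str]],
                undirected: bool = False) -> nx.DiGraph:
    """Interaction graph from (source, relation, target) SIF triples.

    Parallel triples collapse to a single edge; the relation is kept as an
    edge attribute.  ``undirected=True`` adds the reverse of every edge.
    """
    g = nx.DiGraph()
    for src, rel, tgt in edges:
        g.add_edge(src, tgt, relation=rel)
        if undirected:
            g.add_edge(tgt, src, relation=rel)
    return g


def betweenness(graph: nx.DiGraph) -> dict[str, float]:
    """Unnormalized directed betweenness centrality per node."""
    if graph.number_of_nodes() == 0:
        return {}
    return nx.betweenness_centrality(graph, normalized=False)


def stress(graph: nx.DiGraph) -> dict[str, float]:
    """Stress centrality: raw counts of shortest paths through each node.

    Computed from all-pairs BFS distances and path counts:
    g_st(v) = σ(s,v)·σ(v,t) whenever d(s,v) + d(v,t) = d(s,t).
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    dist, sigma = _bfs_counts(graph, nodes)
    scores = np.zeros(n)
    for v in range(n):
        # mask[s, t]: v interior on some shortest s->t path
        dv = dist[:, v][:, None] + dist[v, :][None, :]
        mask = (dv == dist) & np.isfinite(dist)
        mask[v, :] = False
        mask[:, v] = False
        np.fill_diagonal(mask, False)
        contrib = sigma[:, v][:, None] * sigma[v, :][None, :]
        scores[v] = contrib[mask].sum()
    return {nodes[i]: float(scores[i]) for i in range(n)}


def _bfs_counts(graph: nx.DiGraph, nodes: list[str]):
    """All-pairs shortest-path distances and path counts by BFS."""
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = [[idx[w] for w in graph.successors(u)] for u in nodes]
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for w in adj[u]:
                    if np.isinf(dist[s, w]):
                        dist[s, w] = d + 1
                        nxt.append(w)
                    if dist[s, w] == d + 1:
                        sigma[s, w] += sigma[s, u]
            frontier = nxt
            d += 1
    return dist, sigma


def feedback_loops(graph: nx.DiGraph) -> list[list[str]]:
    """Strongly connected components that carry a cycle.

    Returns SCCs of size ≥ 2 plus singleton self-loop nodes, each sorted
    internally and the list ordered by smallest member id.
    """
    loops = []
    for comp in nx.strongly_connected_components(graph):
        if len(comp) >= 2 or any(graph.has_edge(u, u) for u in comp):
            loops.append(sorted(comp))
    return sorted(loops, key=lambda c: c[0])


def centrality_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-node structural summary: degrees, betweenness, stress, and
    membership in a feedback loop."""
    cb = betweenness(graph)
    cs = stress(graph)
    in_loop = {u for comp in feedback_loops(graph) for u in comp}
    rows = [{
        "node": u,
        "in_degree": graph.in_degree(u),
        "out_degree": graph.out_degree(u),
        "betweenness": cb[u],
        "stress": cs[u],
        "in_feedback_loop": u in in_loop,
    } for u in graph.nodes]
    return pd.DataFrame(rows).sort_values("node").reset_index(drop=True)


def top_quantile(table: pd.DataFrame, q: float = 0.25,
                 column: str = "betweenness") -> list[str]:
    """Nodes whose score reaches the top-q band of the nonzero scores.

    The threshold is the (1−q)-quantile of the *nonzero* score
    distribution; ties at the threshold are included.  With all scores
    equal every node is returned.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if table.empty:
        raise ValueError("empty centrality table")
    scores = table[column].to_numpy(dtype=float)
    nonzero = scores[scores > 0]
    if nonzero.size == 0:
        return sorted(table["node"])
    threshold = float(np.quantile(nonzero, 1 - q))
    keep = table.loc[scores >= threshold, "node"]
    return sorted(keep)
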