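"""The central model object: a Boolean network over named nodes.

A :class:`BooleanNetwork` holds an ordered list of node identifiers and one
Boolean update function per node.  Free inputs carry the self-identity
function, so every node has exactly one function and synchronous update is
total.  States are fixed-length 0/1 tuples in node order; for state-space
work they are also encodable as integers with bit *i* holding node *i*
(first node = least-significant bit).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .expr import Const, Expr, Var

__all__ = ["BooleanNetwork", "state_to_int", "int_to_state"]

State = tuple[int, ...]


def state_to_int(state: Sequence[int]) -> int:
    """Pack a 0/1 vector into an integer (first coordinate = bit 0)."""
    code = 0
    for i, bit in enumerate(state):
        if bit:
            code |= 1 << i
    return code


def int_to_state(code: int, n: int) -> State:
    """Unpack an integer into an n-tuple of bits."""
    return tuple((code >> i) & 1 for i in range(n))


class BooleanNetwork:
    """Named nodes plus one Boolean function per node.

    Parameters
    ----------
    functions
        Mapping node id -> expression tree over declared nodes. Iteration
        order of the mapping fixes the node order.
    metadata
        Free-form name/description strings (kept through round-trips where
        the format allows).

    Raises
    ------
    ValueError
        On duplicate/empty identifiers or references to undeclared nodes.
    """

    def __init__(self, functions: Mapping[str, Expr],
                 metadata: Mapping[str, str] | None = None):
        self.nodes: list[str] = list(functions)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if any(not n for n in self.nodes):
            raise ValueError("empty node identifier")
        declared = set(self.nodes)
        for node, fn in functions.items():
            missing = fn.variables() - declared
            if missing:
                raise ValueError(
                    f"function of {node!r} references undeclared node(s) "
                    f"{sorted(missing)}")
        self.functions: dict[str, Expr] = dict(functions)
        self.metadata: dict[str, str] = dict(metadata or {})
        self._index = {n: i for i, n in enumerate(self.nodes)}

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self._index[node]

    @property
    def inputs(self) -> list[str]:
        """Nodes whose function is the identity on themselves."""
        return [n for n in self.nodes if self.functions[n] == Var(n)]

    def regulators(self, node: str) -> list[str]:
        """Nodes appearing in ``node``'s function, in node order."""
        used = self.functions[node].variables()
        return [n for n in self.nodes if n in used]

    # -- evaluation -------------------------------------------------------

    def evaluate(self, node: str, state: Sequence[int]) -> int:
        env = {n: state[i] for n, i in self._index.items()}
        return self.functions[node].evaluate(env)

    def truth_table(self, node: str) -> tuple[tuple[str, ...], tuple[int, ...]]:
        """Exhaustive table of a node's function over its regulators.

        Returns (regulators, outputs) where outputs[k] is the function value
        with regulator bits taken from the binary expansion of k (first
        regulator = least-significant bit).
        """
        regs = tuple(self.regulators(node))
        fn = self.functions[node]
        outs = []
        for k in range(1 << len(regs)):
            env = {r: (k >> i) & 1 for i, r in enumerate(regs)}
            outs.append(fn.evaluate(env))
        return regs, tuple(outs)

    def node_values_over_states(self, chunk: np.ndarray) -> np.ndarray:
        """Evaluate every node's function over an array of packed states.

        ``chunk`` is an integer array of state codes; returns a boolean
        array of shape (n_nodes, len(chunk)) with the next value of each
        node.  Vectorized, used by state-space enumeration.
        """
        bits = {n: ((chunk >> i) & 1).astype(bool)
                for n, i in self._index.items()}
        return np.stack([_eval_np(self.functions[n], bits, len(chunk))
                         for n in self.nodes])

    # -- derived structures ----------------------------------------------

    def interaction_edges(self) -> list[tuple[str, str, str]]:
        """(regulator, relation, target) triples; relation reflects the
        polarity with which the regulator occurs in the target's function:
        'activates' (only plain), 'inhibits' (only negated), 'interacts'
        (both).  Self-identity input functions contribute no edge."""
        edges = []
        for target in self.nodes:
            fn = self.functions[target]
            if fn == Var(target):  # free input
                continue
            pos: set[str] = set()
            neg: set[str] = set()
            for name, negated in fn.literals():
                (neg if negated else pos).add(name)
            for reg in sorted(pos | neg):
                if reg in pos and reg in neg:
                    rel = "interacts"
                elif reg in pos:
                    rel = "activates"
                else:
                    rel = "inhibits"
                edges.append((reg, rel, target))
        return sorted(edges)

    def copy(self, functions: Mapping[str, Expr] | None = None) -> "BooleanNetwork":
        new = dict(self.functions)
        if functions:
            for node, fn in functions.items():
                if node not in new:
                    raise KeyError(f"unknown node {node!r}")
                new[node] = fn
        return BooleanNetwork(new, self.metadata)

    def __repr__(self) -> str:
        return f"BooleanNetwork({len(self)} nodes)"


def _eval_np(expr: Expr, bits: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    from .expr import And, Not, Or
    if isinstance(expr, Var):
        return bits[expr.name]
    if isinstance(expr, Const):
        return np.full(n, bool(expr.value))
    if isinstance(expr, Not):
        return ~_eval_np(expr.operand, bits, n)
    if isinstance(expr, And):
        out = _eval_np(expr.operands[0], bits, n)
        for op in expr.operands[1:]:
            out = out & _eval_np(op, bits, n)
        return out
    if isinstance(expr, Or):
        out = _eval_np(expr.operands[0], bits, n)
        for op in expr.operands[1:]:
            out = out | _eval_np(op, bits, n)
        return out
    raise TypeError(f"unknown expression node {expr!r}")


def truth_tables_equal(a: BooleanNetwork, b: BooleanNetwork) -> bool:
    """True when both networks have the same nodes and per-node truth tables."""
    if a.nodes != b.nodes:
        return False
    return all(a.truth_table(n) == b.truth_table(n) for n in a.nodes)
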