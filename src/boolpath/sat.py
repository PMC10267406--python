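"""Minimal CNF machinery: Tseitin encoding, DIMACS export, DPLL solving.

The attractor-search module frames fixed points and bounded cycles as
satisfiability problems; this module supplies the solver-agnostic CNF
layer.  Clauses are lists of nonzero ints (DIMACS convention: positive =
variable true).  The bundled solver is a plain DPLL with unit propagation
and a most-occurring-variable branching heuristic — entirely adequate for
the encodings produced here, and replaceable by any DIMACS solver.
"""

from __future__ import annotations

from .expr import And, Const, Expr, Not, Or, Var

__all__ = ["CnfBuilder", "solve", "enumerate_models", "to_dimacs"]

Clause = list[int]


class CnfBuilder:
    """Accumulates clauses; Tseitin-encodes expression trees."""

    def __init__(self) -> None:
        self.n_vars = 0
        self.clauses: list[Clause] = []
        self._var_ids: dict[str, int] = {}

    def new_var(self, name: str | None = None) -> int:
        self.n_vars += 1
        if name is not None:
            self._var_ids[name] = self.n_vars
        return self.n_vars

    def var(self, name: str) -> int:
        if name not in self._var_ids:
            self.new_var(name)
        return self._var_ids[name]

    def add(self, clause: Clause) -> None:
        self.clauses.append(clause)

    def add_expr_literal(self, expr: Expr, env: dict[str, int]) -> int:
        """Return a literal equivalent to ``expr`` (variables mapped through
        ``env``), adding Tseitin clauses as needed."""
        if isinstance(expr, Var):
            return env[expr.name]
        if isinstance(expr, Const):
            lit = self.new_var()
            self.add([lit] if expr.value else [-lit])
            return lit
        if isinstance(expr, Not):
            return -self.add_expr_literal(expr.operand, env)
        if isinstance(expr, (And, Or)):
            lits = [self.add_expr_literal(op, env) for op in expr.operands]
            out = self.new_var()
            if isinstance(expr, And):
                # out <-> AND(lits)
                for l in lits:
                    self.add([-out, l])
                self.add([out] + [-l for l in lits])
            else:
                for l in lits:
                    self.add([-l, out])
                self.add([-out] + lits)
            return out
        raise TypeError(f"unknown expression node {expr!r}")

    def add_iff(self, a: int, b: int) -> None:
        self.add([-a, b])
        self.add([a, -b])


def to_dimacs(n_vars: int, clauses: list[Clause]) -> str:
    lines = [f"p cnf {n_vars} {len(clauses)}"]
    lines += [" ".join(map(str, c)) + " 0" for c in clauses]
    return "\n".join(lines) + "\n"


def solve(n_vars: int, clauses: list[Clause]) -> list[int] | None:
    """DPLL with unit propagation.  Returns a model as a list of signed
    literals (index order), or None if unsatisfiable."""
    import sys
    if sys.getrecursionlimit() < 10 * n_vars + 1000:
        sys.setrecursionlimit(10 * n_vars + 1000)
    assign: dict[int, bool] = {}
    # occurrence counts for branching
    occur = [0] * (n_vars + 1)
    for c in clauses:
        for lit in c:
            occur[abs(lit)] += 1

    def value(lit: int) -> bool | None:
        v = assign.get(abs(lit))
        if v is None:
            return None
        return v if lit > 0 else not v

    def propagate(trail: list[int]) -> bool:
        changed = True
        while changed:
            changed = False
            for c in clauses:
                unassigned = None
                n_unassigned = 0
                sat = False
                for lit in c:
                    v = value(lit)
                    if v is True:
                        sat = True
                        break
                    if v is None:
                        unassigned = lit
                        n_unassigned += 1
                if sat:
                    continue
                if n_unassigned == 0:
                    return False
                if n_unassigned == 1:
                    var = abs(unassigned)
                    assign[var] = unassigned > 0
                    trail.append(var)
                    changed = True
        return True

    def backtrack() -> bool:
        trail: list[int] = []
        if not propagate(trail):
            for v in trail:
                del assign[v]
            return False
        free = [v for v in range(1, n_vars + 1) if v not in assign]
        if not free:
            return True
        var = max(free, key=lambda v: occur[v])
        for val in (True, False):
            assign[var] = val
            if backtrack():
                return True
            del assign[var]
        for v in trail:
            del assign[v]
        return False

    if not backtrack():
        return None
    return [v if assign.get(v, False) else -v for v in range(1, n_vars + 1)]


def enumerate_models(n_vars: int, clauses: list[Clause],
                     project: list[int], limit: int | None = None):
    """Yield assignments to ``project`` variables over all models, blocking
    each found projection with an added clause."""
    clauses = list(clauses)
    found = 0
    while limit is None or found < limit:
        model = solve(n_vars, clauses)
        if model is None:
            return
        projection = tuple(1 if model[v - 1] > 0 else 0 for v in project)
        yield projection
        clauses.append([-v if bit else v
                        for v, bit in zip(project, projection)])
        found += 1
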