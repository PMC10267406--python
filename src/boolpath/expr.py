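"""Boolean expression trees and the plain-text rule grammar.

Expressions are immutable trees over AND / OR / NOT / variable / constant.
The concrete grammar used by rule files is::

    expr   := term ('|' term)*
    term   := factor ('&' factor)*
    factor := '!' factor | '(' expr ')' | '0' | '1' | identifier

Identifiers match ``[A-Za-z_][A-Za-z0-9_]*``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "Expr", "Var", "Const", "Not", "And", "Or",
    "parse_expr", "ExprSyntaxError",
]


class Expr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> set[str]:
        """All variable names referenced in the tree."""
        out: set[str] = set()
        stack: list[Expr] = [self]
        while stack:
            e = stack.pop()
            if isinstance(e, Var):
                out.add(e.name)
            elif isinstance(e, Not):
                stack.append(e.operand)
            elif isinstance(e, (And, Or)):
                stack.extend(e.operands)
        return out

    def literals(self) -> Iterator[tuple[str, bool]]:
        """Yield (variable, negated) pairs, one per literal occurrence."""
        stack: list[tuple[Expr, bool]] = [(self, False)]
        while stack:
            e, neg = stack.pop()
            if isinstance(e, Var):
                yield (e.name, neg)
            elif isinstance(e, Not):
                stack.append((e.operand, not neg))
            elif isinstance(e, (And, Or)):
                stack.extend((op, neg) for op in e.operands)

    def __and__(self, other: "Expr") -> "Expr":
        return And((self, other))

    def __or__(self, other: "Expr") -> "Expr":
        return Or((self, other))

    def __invert__(self) -> "Expr":
        return Not(self)


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, env: Mapping[str, int]) -> int:
        return int(env[self.name])

    def __str__(self) -> str:
        return self.name

    def __and__(self, other: Expr) -> Expr:  # keep dataclass from hiding mixins
        return And((self, other))

    def __or__(self, other: Expr) -> Expr:
        return Or((self, other))

    def __invert__(self) -> Expr:
        return Not(self)


@dataclass(frozen=True)
class Const(Expr):
    value: int  # 0 or 1

    def evaluate(self, env: Mapping[str, int]) -> int:
        return self.value

    def __str__(self) -> str:
        return str(self.value)


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, env: Mapping[str, int]) -> int:
        return 1 - self.operand.evaluate(env)

    def __str__(self) -> str:
        inner = str(self.operand)
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, env: Mapping[str, int]) -> int:
        return int(all(op.evaluate(env) for op in self.operands))

    def __str__(self) -> str:
        parts = []
        for op in self.operands:
            s = str(op)
            if isinstance(op, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, env: Mapping[str, int]) -> int:
        return int(any(op.evaluate(env) for op in self.operands))

    def __str__(self) -> str:
        return " | ".join(str(op) for op in self.operands)


def and_all(exprs: list[Expr]) -> Expr:
    """Conjunction of a list; empty list is TRUE, singleton unwrapped."""
    if not exprs:
        return Const(1)
    if len(exprs) == 1:
        return exprs[0]
    return And(tuple(exprs))


def or_all(exprs: list[Expr]) -> Expr:
    """Disjunction of a list; empty list is FALSE, singleton unwrapped."""
    if not exprs:
        return Const(0)
    if len(exprs) == 1:
        return exprs[0]
    return Or(tuple(exprs))


class ExprSyntaxError(ValueError):
    """Malformed Boolean expression text."""


class _Tokenizer:
    _PUNCT = set("&|!()")

    def __init__(self, text: str):
        self.tokens: list[str] = []
        i, n = 0, len(text)
        while i < n:
            c = text[i]
            if c.isspace():
                i += 1
            elif c in self._PUNCT:
                self.tokens.append(c)
                i += 1
            elif c.isalpha() or c == "_" or c.isdigit():
                j = i
                while j < n and (text[j].isalnum() or text[j] == "_"):
                    j += 1
                self.tokens.append(text[i:j])
                i = j
            else:
                raise ExprSyntaxError(f"unexpected character {c!r}")
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str | None:
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok


def parse_expr(text: str) -> Expr:
    """Parse rule-grammar text into an expression tree."""
    tz = _Tokenizer(text)
    expr = _parse_or(tz)
    if tz.peek() is not None:
        raise ExprSyntaxError(f"trailing input at token {tz.peek()!r}")
    return expr


def _parse_or(tz: _Tokenizer) -> Expr:
    parts = [_parse_and(tz)]
    while tz.peek() == "|":
        tz.next()
        parts.append(_parse_and(tz))
    return parts[0] if len(parts) == 1 else Or(tuple(parts))


def _parse_and(tz: _Tokenizer) -> Expr:
    parts = [_parse_factor(tz)]
    while tz.peek() == "&":
        tz.next()
        parts.append(_parse_factor(tz))
    return parts[0] if len(parts) == 1 else And(tuple(parts))


def _parse_factor(tz: _Tokenizer) -> Expr:
    tok = tz.next()
    if tok is None:
        raise ExprSyntaxError("unexpected end of expression")
    if tok == "!":
        return Not(_parse_factor(tz))
    if tok == "(":
        inner = _parse_or(tz)
        if tz.next() != ")":
            raise ExprSyntaxError("missing closing parenthesis")
        return inner
    if tok in ("0", "1"):
        return Const(int(tok))
    if tok in ("&", "|", ")"):
        raise ExprSyntaxError(f"unexpected token {tok!r}")
    if tok[0].isdigit():
        raise ExprSyntaxError(f"invalid identifier {tok!r}")
    return Var(tok)
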