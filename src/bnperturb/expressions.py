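"""Boolean expression trees and the rule-expression parser.

Expressions are immutable trees over node references, the literals 0/1, and
the connectives NOT, AND, OR.  The textual dialect accepted is the common
BNet-style one: ``&``/``AND``, ``|``/``OR``, ``!``/``~``/``NOT`` (operator
words case-insensitive), with parentheses.
"""

from __future__ import annotations

import re
from collections.abc import Mapping, Sequence

import numpy as np

__all__ = [
    "Expr",
    "Var",
    "Lit",
    "Not",
    "And",
    "Or",
    "ParseError",
    "parse_expression",
    "truth_table",
    "MAX_FAN_IN",
]

#: Hard cap on the number of distinct variables a single rule may reference;
#: truth tables are enumerated over referenced inputs, so 2**MAX_FAN_IN rows.
MAX_FAN_IN = 20


class ParseError(ValueError):
    """Raised when rule text cannot be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class Expr:
    """Base class for Boolean expression nodes."""

    __slots__ = ()

    def evaluate(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        out: set[str] = set()
        self._collect(out)
        return frozenset(out)

    def _collect(self, out: set[str]) -> None:
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "Expr"]) -> "Expr":
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self!s})"


class Var(Expr):
    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def evaluate(self, env):
        return int(env[self.name])

    def _collect(self, out):
        out.add(self.name)

    def substitute(self, mapping):
        return mapping.get(self.name, self)

    def __str__(self):
        return self.name

    def __eq__(self, other):
        return isinstance(other, Var) and other.name == self.name

    def __hash__(self):
        return hash(("Var", self.name))


class Lit(Expr):
    __slots__ = ("value",)

    def __init__(self, value: int):
        if value not in (0, 1):
            raise ValueError(f"literal must be 0 or 1, got {value!r}")
        self.value = int(value)

    def evaluate(self, env):
        return self.value

    def _collect(self, out):
        pass

    def substitute(self, mapping):
        return self

    def __str__(self):
        return str(self.value)

    def __eq__(self, other):
        return isinstance(other, Lit) and other.value == self.value

    def __hash__(self):
        return hash(("Lit", self.value))


class Not(Expr):
    __slots__ = ("operand",)

    def __init__(self, operand: Expr):
        self.operand = operand

    def evaluate(self, env):
        return 1 - self.operand.evaluate(env)

    def _collect(self, out):
        self.operand._collect(out)

    def substitute(self, mapping):
        return Not(self.operand.substitute(mapping))

    def __str__(self):
        inner = self.operand
        if isinstance(inner, (Var, Lit, Not)):
            return f"!{inner}"
        return f"!({inner})"

    def __eq__(self, other):
        return isinstance(other, Not) and other.operand == self.operand

    def __hash__(self):
        return hash(("Not", self.operand))


class _Binary(Expr):
    __slots__ = ("left", "right")
    _sym = "?"

    def __init__(self, left: Expr, right: Expr):
        self.left = left
        self.right = right

    def _collect(self, out):
        self.left._collect(out)
        self.right._collect(out)

    def substitute(self, mapping):
        return type(self)(self.left.substitute(mapping), self.right.substitute(mapping))

    def __eq__(self, other):
        return (
            type(other) is type(self)
            and other.left == self.left
            and other.right == self.right
        )

    def __hash__(self):
        return hash((type(self).__name__, self.left, self.right))


class And(_Binary):
    __slots__ = ()
    _sym = "&"

    def evaluate(self, env):
        return self.left.evaluate(env) & self.right.evaluate(env)

    def __str__(self):
        parts = []
        for side in (self.left, self.right):
            if isinstance(side, Or):
                parts.append(f"({side})")
            else:
                parts.append(str(side))
        return " & ".join(parts)


class Or(_Binary):
    __slots__ = ()
    _sym = "|"

    def evaluate(self, env):
        return self.left.evaluate(env) | self.right.evaluate(env)

    def __str__(self):
        return f"{self.left} | {self.right}"


_TOKEN = re.compile(
    r"""\s*(?:
        (?P<lpar>\() |
        (?P<rpar>\)) |
        (?P<and>&+|\bAND\b) |
        (?P<or>\|+|\bOR\b) |
        (?P<not>!|~|\bNOT\b) |
        (?P<name>[A-Za-z0-9_.]+)
    )""",
    re.IGNORECASE | re.VERBOSE,
)


def _tokenize(text: str, line: int | None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ParseError(f"unexpected character {rest[0]!r} in expression", line)
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    return tokens


class _Parser:
    """Recursive-descent parser: or-expr > and-expr > unary > atom."""

    def __init__(self, tokens: list[tuple[str, str]], line: int | None):
        self.tokens = tokens
        self.i = 0
        self.line = line

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def take(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> Expr:
        if not self.tokens:
            raise ParseError("empty expression", self.line)
        expr = self.or_expr()
        if self.i != len(self.tokens):
            raise ParseError(
                f"trailing input near {self.tokens[self.i][1]!r}", self.line
            )
        return expr

    def or_expr(self) -> Expr:
        node = self.and_expr()
        while self.peek() == "or":
            self.take()
            node = Or(node, self.and_expr())
        return node

    def and_expr(self) -> Expr:
        node = self.unary()
        while self.peek() == "and":
            self.take()
            node = And(node, self.unary())
        return node

    def unary(self) -> Expr:
        if self.peek() == "not":
            self.take()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> Expr:
        kind = self.peek()
        if kind == "lpar":
            self.take()
            node = self.or_expr()
            if self.peek() != "rpar":
                raise ParseError("unbalanced parenthesis", self.line)
            self.take()
            return node
        if kind == "name":
            _, text = self.take()
            if text == "0" or text == "1":
                return Lit(int(text))
            return Var(text)
        got = self.tokens[self.i][1] if self.i < len(self.tokens) else "end of input"
        raise ParseError(f"expected a node name, literal or '(', got {got!r}", self.line)


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a single Boolean expression from text."""
    return _Parser(_tokenize(text, line), line).parse()


def truth_table(expr: Expr, variables: Sequence[str]) -> np.ndarray:
    """Enumerate ``expr`` over all assignments of ``variables``.

    Returns a uint8 array of length ``2**len(variables)``; variable ``j``
    contributes bit ``j`` (least significant first) of the row index.
    """
    k = len(variables)
    if k > MAX_FAN_IN:
        raise ValueError(
            f"rule fan-in {k} exceeds the supported maximum of {MAX_FAN_IN}"
        )
    table = np.empty(1 << k, dtype=np.uint8)
    env: dict[str, int] = {}
    for idx in range(1 << k):
        for j, name in enumerate(variables):
            env[name] = (idx >> j) & 1
        table[idx] = expr.evaluate(env)
    return table
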