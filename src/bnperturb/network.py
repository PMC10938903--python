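"""Boolean network representation, rule-file parsing, classification, reduction.

A :class:`BooleanNetwork` is an ordered list of named nodes, each carrying a
Boolean update expression.  Node order is stable and defines state-vector
index positions everywhere else in the package.  Every rule is compiled at
construction time to a truth table over its referenced inputs, which is what
classification and simulation actually consume; the expression tree is kept
for serialization and algebraic reduction.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .expressions import (
    And,
    Expr,
    Lit,
    Not,
    Or,
    ParseError,
    Var,
    parse_expression,
    truth_table,
)

__all__ = [
    "BooleanNetwork",
    "CompiledRule",
    "NodeClassification",
    "PercolationResult",
    "parse_network",
    "classify_nodes",
    "percolate_sources",
    "eliminate_node",
]

CONSTANT = "constant"
SOURCE = "source"
INTERNAL = "internal"


@dataclass(frozen=True)
class CompiledRule:
    """A rule lowered to a lookup table over its referenced node indices."""

    inputs: tuple[int, ...]  # indices into the network node order, LSB first
    table: np.ndarray  # uint8, length 2**len(inputs)


class BooleanNetwork:
    """An ordered collection of Boolean update rules.

    Parameters
    ----------
    node_names:
        Unique node identifiers; order defines state-vector positions.
    rules:
        One expression per node, referencing only declared node names.
    """

    def __init__(
        self,
        node_names: Sequence[str],
        rules: Sequence[Expr],
        *,
        allow_empty: bool = False,
    ):
        names = tuple(node_names)
        if len(names) != len(set(names)):
            seen: set[str] = set()
            for n in names:
                if n in seen:
                    raise ValueError(f"duplicate node name {n!r}")
                seen.add(n)
        if not names and not allow_empty:
            raise ValueError("a Boolean network must declare at least one node")
        if len(rules) != len(names):
            raise ValueError("need exactly one rule per node")
        self.node_names: tuple[str, ...] = names
        self.rules: tuple[Expr, ...] = tuple(rules)
        self._index = {n: i for i, n in enumerate(names)}
        self._compiled = tuple(self._compile(rule) for rule in self.rules)

    def _compile(self, rule: Expr) -> CompiledRule:
        refs = rule.variables()
        for name in refs:
            if name not in self._index:
                raise ValueError(f"rule references undeclared node {name!r}")
        ordered = sorted(refs, key=self._index.__getitem__)
        return CompiledRule(
            inputs=tuple(self._index[n] for n in ordered),
            table=truth_table(rule, ordered),
        )

    # -- basic protocol ---------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.node_names)

    def __len__(self) -> int:
        return self.N

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def compiled(self) -> tuple[CompiledRule, ...]:
        return self._compiled

    def rule_of(self, name: str) -> Expr:
        return self.rules[self._index[name]]

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return self.node_names == other.node_names and self.rules == other.rules

    def __repr__(self) -> str:
        return f"BooleanNetwork(N={self.N}, nodes={list(self.node_names)!r})"

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_rules(
        cls, pairs: Iterable[tuple[str, Expr]], *, allow_empty: bool = False
    ) -> "BooleanNetwork":
        names, rules = [], []
        for name, rule in pairs:
            names.append(name)
            rules.append(rule)
        return cls(names, rules, allow_empty=allow_empty)

    @classmethod
    def from_truth_tables(
        cls,
        node_names: Sequence[str],
        inputs: Sequence[Sequence[int]],
        tables: Sequence[Sequence[int]],
    ) -> "BooleanNetwork":
        """Build a network from explicit per-node truth tables.

        ``inputs[j]`` lists the regulator indices of node ``j`` (LSB first in
        the table row index); ``tables[j]`` has ``2**len(inputs[j])`` binary
        entries.
        """
        names = tuple(node_names)
        rules = []
        for inp, table in zip(inputs, tables, strict=True):
            table = np.asarray(table, dtype=np.uint8)
            if table.shape != (1 << len(inp),):
                raise ValueError("truth table length must be 2**fan_in")
            rules.append(_table_to_expr([names[i] for i in inp], table))
        return cls(names, rules)

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        """Canonical rule-file form: one ``target, expression`` line per node."""
        lines = ["targets, factors"]
        lines.extend(f"{n}, {r}" for n, r in zip(self.node_names, self.rules))
        return "\n".join(lines) + "\n"


def _table_to_expr(var_names: Sequence[str], table: np.ndarray) -> Expr:
    """Minterm (DNF) expression realizing ``table`` over ``var_names``."""
    if not table.any():
        return Lit(0)
    if table.all():
        return Lit(1)
    minterms: list[Expr] = []
    for idx in np.flatnonzero(table):
        term: Expr | None = None
        for j, name in enumerate(var_names):
            lit: Expr = Var(name) if (int(idx) >> j) & 1 else Not(Var(name))
            term = lit if term is None else And(term, lit)
        minterms.append(term)  # type: ignore[arg-type]
    expr = minterms[0]
    for t in minterms[1:]:
        expr = Or(expr, t)
    return expr


# ---------------------------------------------------------------------------
# Rule-file parsing
# ---------------------------------------------------------------------------

def parse_network(text: str) -> BooleanNetwork:
    """Parse rule text: one ``target, expression`` (or ``target = expression``)
    per non-comment line.

    ``#`` starts a comment; an optional ``targets, factors`` header line is
    skipped; blank lines are ignored.
    """
    names: list[str] = []
    exprs: list[Expr] = []
    lines_of: dict[str, int] = {}
    pending: list[tuple[str, str, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," in line:
            target, expr_text = line.split(",", 1)
        elif "=" in line:
            target, expr_text = line.split("=", 1)
        else:
            raise ParseError(
                "expected 'target, expression' or 'target = expression'", lineno
            )
        target = target.strip()
        if not target:
            raise ParseError("missing target name", lineno)
        if target.lower() == "targets" and expr_text.strip().lower() == "factors":
            continue  # header line
        if target in lines_of:
            raise ParseError(
                f"duplicate target {target!r} (first declared on line {lines_of[target]})",
                lineno,
            )
        lines_of[target] = lineno
        pending.append((target, expr_text, lineno))
    if not pending:
        raise ParseError("no rules found in input")
    for target, expr_text, lineno in pending:
        exprs.append(parse_expression(expr_text, lineno))
        names.append(target)
    declared = set(names)
    for (target, _, lineno), expr in zip(pending, exprs):
        for ref in sorted(expr.variables()):
            if ref not in declared:
                raise ParseError(
                    f"rule for {target!r} references undeclared node {ref!r}", lineno
                )
    return BooleanNetwork(names, exprs)


# ---------------------------------------------------------------------------
# Semantic classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeClassification:
    """Per-node label among constant / source / internal (semantic)."""

    labels: tuple[str, ...]
    constant_values: tuple[int | None, ...] = field(default=(), repr=False)

    @property
    def sources(self) -> tuple[int, ...]:
        return tuple(i for i, l in enumerate(self.labels) if l == SOURCE)

    @property
    def constants(self) -> tuple[int, ...]:
        return tuple(i for i, l in enumerate(self.labels) if l == CONSTANT)

    @property
    def internals(self) -> tuple[int, ...]:
        return tuple(i for i, l in enumerate(self.labels) if l == INTERNAL)


def _classify_compiled(node_index: int, comp: CompiledRule) -> tuple[str, int | None]:
    table = comp.table
    first = int(table[0])
    if (table == first).all():
        return CONSTANT, first
    if node_index in comp.inputs:
        pos = comp.inputs.index(node_index)
        idx = np.arange(table.size)
        if np.array_equal(table, ((idx >> pos) & 1).astype(np.uint8)):
            return SOURCE, None
    return INTERNAL, None


def classify_nodes(net: BooleanNetwork) -> NodeClassification:
    """Classify each node by truth-table equivalence, not syntax.

    A node is *constant* iff its rule's output is independent of every input
    (equivalent to 0 or 1), *source* iff the rule is equivalent to the node's
    own current value, and *internal* otherwise.
    """
    labels: list[str] = []
    values: list[int | None] = []
    for j, comp in enumerate(net.compiled):
        label, value = _classify_compiled(j, comp)
        labels.append(label)
        values.append(value)
    return NodeClassification(tuple(labels), tuple(values))


# ---------------------------------------------------------------------------
# Reduction operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PercolationResult:
    network: BooleanNetwork  # residual network (may be empty)
    fixed: dict[str, int]  # nodes removed, in percolation order, with values


def percolate_sources(
    net: BooleanNetwork, source_values: Mapping[str, int]
) -> PercolationResult:
    """Fix the given source/constant nodes and propagate until quiescence.

    The fixed values are substituted into every rule; any node whose rule
    thereby becomes semantically constant is fixed at that constant and the
    substitution repeats.  Nodes that were constant in the *original* network
    are retained unless explicitly listed.  Dynamics of the surviving nodes
    are unchanged for initial states consistent with the fixed values.
    """
    cls = classify_nodes(net)
    pending: dict[str, int] = {}
    for name, value in source_values.items():
        if name not in net.node_names:
            raise ValueError(f"unknown node {name!r}")
        j = net.index(name)
        label = cls.labels[j]
        if label == INTERNAL:
            raise ValueError(
                f"cannot fix internal node {name!r}; only source or constant nodes"
            )
        value = int(value)
        if value not in (0, 1):
            raise ValueError(f"fixed value for {name!r} must be 0 or 1")
        if label == CONSTANT and value != cls.constant_values[j]:
            raise ValueError(
                f"constant node {name!r} holds {cls.constant_values[j]} but was "
                f"assigned {value}"
            )
        pending[name] = value

    originally_constant = {net.node_names[i] for i in cls.constants}
    exprs: dict[str, Expr] = dict(zip(net.node_names, net.rules))
    remaining = list(net.node_names)
    fixed: dict[str, int] = {}
    while pending:
        subs = {name: Lit(v) for name, v in pending.items()}
        fixed.update(pending)
        remaining = [n for n in remaining if n not in pending]
        for n in remaining:
            exprs[n] = exprs[n].substitute(subs)
        pending = {}
        for n in remaining:
            if n in originally_constant:
                continue
            value = _constant_value(exprs[n])
            if value is not None:
                pending[n] = value
    residual = BooleanNetwork(
        remaining, [exprs[n] for n in remaining], allow_empty=True
    )
    return PercolationResult(network=residual, fixed=fixed)


def _constant_value(expr: Expr) -> int | None:
    refs = sorted(expr.variables())
    table = truth_table(expr, refs)
    first = int(table[0])
    if (table == first).all():
        return first
    return None


def eliminate_node(net: BooleanNetwork, node: str) -> BooleanNetwork:
    """Remove a self-edge-free node by inlining its rule into its targets.

    Steady states of the reduced network correspond one-to-one to steady
    states of the original restricted to the remaining nodes.
    """
    if node not in net.node_names:
        raise ValueError(f"unknown node {node!r}")
    rule = net.rule_of(node)
    if node in rule.variables():
        raise ValueError(f"node {node!r} has a self-edge and cannot be eliminated")
    subs = {node: rule}
    pairs = [
        (n, r.substitute(subs))
        for n, r in zip(net.node_names, net.rules)
        if n != node
    ]
    if not pairs:
        raise ValueError("cannot eliminate the only node of a network")
    return BooleanNetwork.from_rules(pairs)
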