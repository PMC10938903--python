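import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnperturb import (
    BooleanNetwork,
    ParseError,
    classify_nodes,
    eliminate_node,
    parse_network,
    percolate_sources,
    steady_states,
)
from bnperturb.expressions import And, Lit, Not, Or, Var


def all_assignments(net):
    for values in itertools.product((0, 1), repeat=net.N):
        yield dict(zip(net.node_names, values))


def truth_rows(net):
    """Full N-input truth table of every rule (independent of compilation)."""
    return [
        tuple(rule.evaluate(env) for env in all_assignments(net))
        for rule in net.rules
    ]


# -- parse_network ----------------------------------------------------------

def test_parse_mutual_inhibition(mutual_inhibition):
    net = parse_network("A, !B\nB, !A")
    assert net.node_names == ("A", "B")
    # A* = NOT B, B* = NOT A on every assignment
    for env in all_assignments(net):
        assert net.rules[0].evaluate(env) == 1 - env["B"]
        assert net.rules[1].evaluate(env) == 1 - env["A"]
    assert net == mutual_inhibition


def test_parse_identity_rule_is_source():
    net = parse_network("A, A")
    assert classify_nodes(net).labels == ("source",)


def test_parse_contradiction_is_constant():
    # truth-table oracle: B & !B is 0 on all four assignments
    net = parse_network("A, (B & !B)\nB, B")
    rule = net.rules[0]
    assert all(rule.evaluate(env) == 0 for env in all_assignments(net))
    assert classify_nodes(net).labels == ("constant", "source")


def test_parse_accepts_equals_separator_and_comments():
    net = parse_network(
        "# a comment\ntargets, factors\nA = !B  # trailing\n\nB = !A\n"
    )
    assert net.node_names == ("A", "B")


def test_parse_undeclared_identifier_names_it():
    with pytest.raises(ParseError, match=r"(?s)line 2.*'C'"):
        parse_network("A, !B\nB, C")


def test_parse_duplicate_target():
    with pytest.raises(ParseError, match="duplicate"):
        parse_network("A, !A\nA, A")


def test_parse_empty_input():
    with pytest.raises(ParseError):
        parse_network("# only a comment\n")


def test_declaration_order_defines_indices():
    net = parse_network("Z, Q\nQ, Z")
    assert net.node_names == ("Z", "Q")
    assert net.index("Q") == 1


# -- classify_nodes ---------------------------------------------------------

def test_classify_mutual_inhibition_internal(mutual_inhibition):
    assert classify_nodes(mutual_inhibition).labels == ("internal", "internal")


def test_classify_source_node(oscillator_plus_source):
    assert classify_nodes(oscillator_plus_source).labels == ("internal", "source")


def test_classify_tautology_constant():
    net = parse_network("A, A | !A")
    cls = classify_nodes(net)
    assert cls.labels == ("constant",)
    assert cls.constant_values == (1,)


def test_classify_all_constant(all_constant):
    cls = classify_nodes(all_constant)
    assert cls.labels == ("constant", "constant")
    assert cls.constant_values == (0, 1)


def test_classification_is_semantic_not_syntactic():
    # double negation and redundant conjuncts must not change the labels
    net = parse_network("A, !!A\nB, B & (A | !A)\nC, !(C) | C")
    assert classify_nodes(net).labels == ("source", "source", "constant")


# -- percolate_sources ------------------------------------------------------

def test_percolation_cascade_to_empty_core():
    net = parse_network("A, A\nB, A & C\nC, B")
    res = percolate_sources(net, {"A": 0})
    assert res.fixed == {"A": 0, "B": 0, "C": 0}
    assert res.network.N == 0


def test_percolation_leaves_independent_node():
    net = parse_network("A, A\nB, !B")
    res = percolate_sources(net, {"A": 1})
    assert res.fixed == {"A": 1}
    assert res.network.node_names == ("B",)
    # B's dynamics unchanged
    assert res.network.rules[0].evaluate({"B": 0}) == 1
    assert res.network.rules[0].evaluate({"B": 1}) == 0


def test_percolation_noop_without_sources(mutual_inhibition):
    res = percolate_sources(mutual_inhibition, {})
    assert res.fixed == {}
    assert res.network == mutual_inhibition


def test_percolation_rejects_internal_node(mutual_inhibition):
    with pytest.raises(ValueError, match="internal"):
        percolate_sources(mutual_inhibition, {"A": 1})


def test_percolation_rejects_inconsistent_constant(all_constant):
    with pytest.raises(ValueError, match="holds"):
        percolate_sources(all_constant, {"A": 1})  # A is constant 0


def test_percolation_retains_untouched_constants():
    net = parse_network("A, A\nB, 1\nC, A | B")
    res = percolate_sources(net, {"A": 0})
    # C's rule references B, which stays a node; C is not newly constant
    assert res.fixed == {"A": 0}
    assert res.network.node_names == ("B", "C")


# -- eliminate_node ---------------------------------------------------------

def test_eliminate_simple_chain():
    net = parse_network("A, B\nB, C\nC, A")
    red = eliminate_node(net, "B")
    assert red.node_names == ("A", "C")
    # A* = C, C* = A
    for env in ({"A": a, "C": c} for a in (0, 1) for c in (0, 1)):
        assert red.rules[0].evaluate(env) == env["C"]
        assert red.rules[1].evaluate(env) == env["A"]


def test_eliminate_self_edge_errors(oscillator):
    with pytest.raises(ValueError, match="self-edge"):
        eliminate_node(oscillator, "A")


def test_eliminate_creates_constant():
    net = parse_network("A, B & C\nB, !C\nC, C")
    red = eliminate_node(net, "B")
    assert red.node_names == ("A", "C")
    # A* = (!C) & C == 0 by truth table
    cls = classify_nodes(red)
    assert cls.labels[0] == "constant"
    assert cls.constant_values[0] == 0


# -- reduction preserves steady states --------------------------------------

def project(state, keep_bits):
    return sum(((state >> b) & 1) << j for j, b in enumerate(keep_bits))


@pytest.mark.parametrize(
    "rules,node",
    [
        ("A, B\nB, C\nC, A", "B"),
        ("A, B & C\nB, !C\nC, C", "B"),
        ("A, B | C\nB, A & C\nC, !A", "B"),
        ("A, !B\nB, !A\nC, A & B\nD, C | B", "C"),
    ],
)
def test_eliminate_preserves_steady_states(rules, node):
    net = parse_network(rules)
    red = eliminate_node(net, node)
    keep = [net.index(n) for n in red.node_names]
    original = sorted({project(s, keep) for s in steady_states(net)})
    assert sorted(steady_states(red)) == original


@pytest.mark.parametrize(
    "rules,fixed",
    [
        ("A, A\nB, A & C\nC, B | C", {"A": 1}),
        ("A, A\nB, !A | B\nC, B & !C", {"A": 0}),
        ("S, S\nA, S & B\nB, A | !S", {"S": 1}),
    ],
)
def test_percolation_preserves_consistent_steady_states(rules, fixed):
    net = parse_network(rules)
    res = percolate_sources(net, fixed)
    keep = [net.index(n) for n in res.network.node_names]
    fixed_bits = {net.index(n): v for n, v in res.fixed.items()}
    consistent = [
        s
        for s in steady_states(net)
        if all((s >> b) & 1 == v for b, v in fixed_bits.items())
    ]
    projected = sorted({project(s, keep) for s in consistent})
    assert sorted(steady_states(res.network)) == projected


# -- serialization round trip -----------------------------------------------

def test_round_trip_fixture_networks(any_fixture):
    reparsed = parse_network(any_fixture.to_text())
    assert reparsed.node_names == any_fixture.node_names
    assert truth_rows(reparsed) == truth_rows(any_fixture)


# -- property tests ---------------------------------------------------------

NAMES = ("A", "B", "C", "D")


def rule_exprs():
    leaf = st.one_of(
        st.sampled_from(NAMES).map(Var),
        st.sampled_from([0, 1]).map(Lit),
    )
    return st.recursive(
        leaf,
        lambda ch: st.one_of(
            ch.map(Not),
            st.tuples(ch, ch).map(lambda p: And(*p)),
            st.tuples(ch, ch).map(lambda p: Or(*p)),
        ),
        max_leaves=8,
    )


networks = st.lists(rule_exprs(), min_size=4, max_size=4).map(
    lambda rules: BooleanNetwork(NAMES, rules)
)


@given(networks)
def test_round_trip_random_networks(net):
    reparsed = parse_network(net.to_text())
    assert truth_rows(reparsed) == truth_rows(net)


def equivalent_rewrite(expr, variant):
    if variant == 0:
        return Not(Not(expr))
    if variant == 1:
        return Or(expr, expr)
    if variant == 2:
        return And(expr, Or(Var("A"), Not(Var("A"))))
    return Or(And(expr, Var("B")), And(expr, Not(Var("B"))))


@given(networks, st.lists(st.integers(0, 3), min_size=4, max_size=4))
def test_classification_invariant_under_equivalent_rewrites(net, variants):
    rewritten = BooleanNetwork(
        net.node_names,
        [equivalent_rewrite(r, v) for r, v in zip(net.rules, variants)],
    )
    assert truth_rows(rewritten) == truth_rows(net)
    assert classify_nodes(rewritten).labels == classify_nodes(net).labels
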