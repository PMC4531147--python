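"""Parsing, serialization round-trips, macro expansion, variable extraction."""

import pytest
from hypothesis import given, settings, strategies as st

import genotiler as gt
from genotiler.lang import Label, Interval, Point, RuleKind


def test_declaration_line():
    p = gt.parse_program("Cro:{low<high}\nCro(low) -> Cro(high)")
    (d,) = p.declarations
    assert d.agent == gt.const("Cro")
    assert d.chain == ("low", "high")
    assert d.unequal == frozenset()


def test_declaration_with_unequal_pairs():
    p = gt.parse_program("G:{Low<Mid<High, a/~b}")
    (d,) = p.declarations
    assert d.chain == ("Low", "Mid", "High")
    assert d.unequal == frozenset({("a", "b")})
    assert d.n_attributes == 5


def test_empty_source_is_empty_program():
    p = gt.parse_program("")
    assert p == gt.Program()
    assert not p.rules and not p.declarations and not p.spots


def test_repressilator_rules_are_persistent_with_negated_effects(repressilator):
    goal, _ = repressilator
    assert len(goal.rules) == 3
    for r in goal.rules:
        assert r.kind is RuleKind.PERSISTENT
        assert all(l.positive for l in r.cause)
        assert all(not l.positive for l in r.effect)


def test_numeric_qualifiers():
    p = gt.parse_program("LacI(0.3) -> LacI[0.1,0.4]")
    (r,) = p.rules
    (c,) = r.cause
    (e,) = r.effect
    assert c.qualifier == Point(0.3)
    assert e.qualifier == Interval(0.1, 0.4)


def test_observation_spot_and_context_and_compartment():
    src = "obs_start:: X\n[K]{\nX -> Y\n}\nNucleus{\nY -> Z\n}\n"
    p = gt.parse_program(src)
    (spot,) = p.spots
    assert spot.label == "start" and spot.observed == gt.lit("X")
    r1, r2 = p.rules
    assert r1.scope.contexts == (gt.AgentRef("K"),)
    assert r2.scope.compartments == ("Nucleus",)


@pytest.mark.parametrize("src, fragment", [
    ("X -> ", "cannot parse"),            # missing effect
    ("X ->> Y", "cannot parse"),          # bad arrow
    ("X:{a<a}", "duplicate"),             # duplicate chain label
    ("Cro(low) -> Cro", "undeclared"),    # constant label without declaration
    ("obs_1:: 3X", "malformed literal"),  # malformed literal
    ("[k]{\nX -> Y", "unclosed"),         # unterminated block
])
def test_parse_errors(src, fragment):
    with pytest.raises(gt.ParseError) as exc:
        gt.parse_program(src)
    assert fragment.lower() in str(exc.value).lower()


def test_parse_error_reports_line_number():
    with pytest.raises(gt.ParseError) as exc:
        gt.parse_program("X -> Y\n???\n")
    assert exc.value.line == 2


# --------------------------------------------------------------------------- #
# round trips


def test_single_rule_round_trip():
    p = gt.parse_program("g1 o-> !g2")
    assert gt.parse_program(gt.serialize_program(p)) == p
    assert "g1 o-> !g2" in gt.serialize_program(p)


def test_fixture_round_trips(fx):
    for key in ("repressilator_goal", "lambda_switch"):
        p = fx[key]
        assert gt.parse_program(gt.serialize_program(p)) == p


def test_scoped_rule_serializes_with_block_prefix():
    p = gt.parse_program("[K]{\nX -> Y\n}")
    text = gt.serialize_program(p)
    assert "[K]{" in text and text.count("}") == 1
    assert gt.parse_program(text) == p


# random surface programs: declarations, scopes, macros, qualifiers ----------

_labels = st.sampled_from(["low", "mid", "high"])
_const_names = st.sampled_from(["Ara", "CI", "Cro", "LacI", "TetR_lite"])
_var_names = st.sampled_from(["g1", "g2", "x"])


@st.composite
def _program(draw):
    declared = draw(st.lists(_const_names, unique=True, max_size=2))
    decls = tuple(gt.AttributeDecl(gt.AgentRef(n), ("low", "mid", "high"))
                  for n in declared)

    def literal(names):
        name = draw(st.one_of(st.sampled_from(names) if names else _var_names,
                              _var_names))
        qual = None
        if gt.AgentRef(name).is_constant:
            if name in declared and draw(st.booleans()):
                qual = Label(draw(_labels))
        elif draw(st.booleans()):
            qual = Label(draw(_labels))
        return gt.StateLiteral(gt.AgentRef(name), draw(st.booleans()), qual)

    scope = gt.Scope(
        contexts=tuple(gt.AgentRef(n) for n in draw(
            st.lists(st.sampled_from(["k1", "Sig"]), unique=True, max_size=1))),
        compartments=tuple(draw(
            st.lists(st.sampled_from(["Nucleus", "Cyto"]), unique=True, max_size=1))),
    )
    rules = []
    for _ in range(draw(st.integers(0, 4))):
        kind = draw(st.sampled_from(list(RuleKind)))
        cause = frozenset(literal(declared) for _ in range(draw(st.integers(1, 2))))
        effect = frozenset(literal(declared) for _ in range(draw(st.integers(1, 2))))
        rules.append(gt.CausalRule(kind, cause, effect,
                                   scope if draw(st.booleans()) else gt.Scope()))
    spots = tuple(gt.ObservationSpot(f"s{i}", literal(declared))
                  for i in range(draw(st.integers(0, 2))))
    return gt.Program(tuple(rules), decls, spots)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_program())
def test_round_trip_is_identity_on_random_programs(p):
    assert gt.parse_program(gt.serialize_program(p)) == p


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_round_trip_on_generated_benchmark_goals(seed):
    cfg = gt.BenchConfig(n_components=5, n_goal_rules=3, n_variables=1,
                         n_constants=6, seed=seed)
    try:
        lib, goal = gt.generate(cfg)
    except gt.InfeasibleConfigError:
        return
    assert gt.parse_program(gt.serialize_program(goal)) == goal
    for comp in lib:
        assert gt.parse_program(gt.serialize_program(comp.program)) == comp.program


# --------------------------------------------------------------------------- #
# macro expansion


def test_strong_inhibition_expansion():
    p = gt.parse_program("Cro:{low<high}\nCI:{low<high}\nCro(low) -- CI(high)")
    e = gt.expand_macros(p)
    texts = {(r.kind, r.cause, r.effect) for r in e.rules}
    cro = gt.StateLiteral(gt.AgentRef("Cro"), True, Label("low"))
    ci = gt.StateLiteral(gt.AgentRef("CI"), True, Label("high"))
    assert texts == {
        (RuleKind.PERSISTENT, frozenset([cro]), frozenset([ci.negated()])),
        (RuleKind.NORMAL, frozenset([cro.negated()]), frozenset([ci])),
    }


def test_strong_activation_expansion():
    p = gt.parse_program("g1 -+ g2")
    e = gt.expand_macros(p)
    g1, g2 = gt.lit("g1"), gt.lit("g2")
    assert {(r.kind, r.cause, r.effect) for r in e.rules} == {
        (RuleKind.PERSISTENT, frozenset([g1]), frozenset([g2])),
        (RuleKind.NORMAL, frozenset([g1.negated()]), frozenset([g2.negated()])),
    }


def test_expansion_passes_primitives_through_and_is_idempotent(fx):
    lam = fx["lambda_switch"]
    once = gt.expand_macros(lam)
    assert len(once.rules) == 4  # two macros, two primitives each
    assert once.is_expanded
    assert gt.expand_macros(once) == once
    prim = gt.parse_program("A -> B\nA o-> B\nA +-> B")
    assert gt.expand_macros(prim) == prim


@settings(max_examples=40, derandomize=True, deadline=None)
@given(_program())
def test_expansion_doubles_macro_rules_and_keeps_the_rest(p):
    n_macro = sum(1 for r in p.rules if not r.kind.is_primitive)
    e = gt.expand_macros(p)
    assert len(e.rules) == len(p.rules) + n_macro
    assert e.is_expanded
    assert gt.expand_macros(e) == e


# --------------------------------------------------------------------------- #
# variables_of


def test_variables_of_repressilator(repressilator):
    goal, _ = repressilator
    assert {a.name for a in gt.variables_of(goal)} == {"g1", "g2"}


def test_variables_of_ground_program(fx):
    assert gt.variables_of(fx["lambda_switch"]) == frozenset()


def test_variables_counted_once_across_sides():
    p = gt.parse_program("v -> v & X")
    assert gt.variables_of(p) == frozenset({gt.var("v")})
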