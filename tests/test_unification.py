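"""Rule unification, the substitution calculus, assembly, and the
brute-force oracle equivalence."""

import pytest
from hypothesis import given, settings, strategies as st

import genotiler as gt
from genotiler.unification import EMPTY_SUBSTITUTION
from .conftest import pipeline_solution_set, small_instance


def _rule(src):
    return gt.parse_program(src).rules[0]


# --------------------------------------------------------------------------- #
# unify_rule


def test_unify_binds_variables_to_component_constants():
    p1 = _rule("g1 o-> !g2")
    q2 = _rule("CI o-> !LacI")
    (s,) = gt.unify_rule(p1, q2)
    assert s.as_dict() == {"g1": "CI", "g2": "LacI"}


def test_unify_respects_an_existing_binding():
    p3 = _rule("TetR_lite o-> !g1")
    q4 = _rule("TetR_lite o-> !GFP")
    fixed = gt.Substitution((("g1", gt.const("CI")),))
    assert gt.unify_rule(p3, q4, fixed) == []          # g1 is already CI
    assert len(gt.unify_rule(p3, q4)) == 1             # otherwise g1 -> GFP


def test_unify_ground_identical_rules_is_identity():
    r = _rule("LacI o-> !TetR_lite")
    assert gt.unify_rule(r, r) == [EMPTY_SUBSTITUTION]


def test_unify_requires_equal_kind_and_cardinalities():
    assert gt.unify_rule(_rule("a -> B"), _rule("C o-> B")) == []
    assert gt.unify_rule(_rule("a -> B"), _rule("C & D -> B")) == []


def test_unify_never_maps_a_variable_to_a_goal_constant(repressilator):
    goal, _ = repressilator
    p1 = _rule("g1 o-> !g2")
    q = _rule("CI o-> !TetR_lite")  # would need g2 -> TetR_lite
    forbidden = gt.constants_of(goal)
    assert gt.unify_rule(p1, q, forbidden=forbidden) == []
    assert len(gt.unify_rule(p1, q)) == 1  # allowed without the goal context


def test_substitution_is_injective_on_variables():
    p = _rule("a & b -> C")
    q = _rule("X & X2 -> C")
    subs = gt.unify_rule(p, q)
    assert all(len(set(s.as_dict().values())) == len(s.as_dict()) for s in subs)
    # both assignments of {a,b} to {X,X2} are found
    assert len(subs) == 2


def test_substitution_merge_conflict():
    s1 = gt.Substitution((("g1", gt.const("CI")),))
    s2 = gt.Substitution((("g1", gt.const("LacI")),))
    with pytest.raises(gt.SubstitutionConflictError):
        s1.merge(s2)


# --------------------------------------------------------------------------- #
# aci_unify on the worked example


def test_aci_unify_accepts_the_surviving_subset(repressilator):
    goal, lib = repressilator
    res = gt.aci_unify(goal, [lib.get(n) for n in ("Q2", "Q1", "Q3")])
    assert len(res) == 1
    (r,) = res
    assert r.components == ("Q1", "Q2", "Q3")
    assert r.substitution.as_dict() == {"g1": "CI", "g2": "LacI"}
    assert set(r.derivation) >= {"Inst(Q1)", "Inst(Q2)", "Inst(Q3)", "Asm"}


def test_aci_unify_rejects_the_conflicting_subset(repressilator):
    goal, lib = repressilator
    assert gt.aci_unify(goal, [lib.get(n) for n in ("Q2", "Q1", "Q4")]) == []


def test_aci_unify_ground_textual_cover():
    lib = gt.ComponentLibrary((
        gt.Component("D1", gt.parse_program("A -> B")),
        gt.Component("D2", gt.parse_program("B -> C")),
    ))
    goal = gt.parse_program("A -> B\nB -> C")
    (r,) = gt.aci_unify(goal, list(lib))
    assert r.substitution.as_dict() == {}
    assert r.components == ("D1", "D2")


def test_aci_unify_invariant_under_permutation_and_duplication(repressilator):
    goal, lib = repressilator
    base = [lib.get(n) for n in ("Q1", "Q2", "Q3")]
    ref = [(r.components, r.substitution.items) for r in gt.aci_unify(goal, base)]
    for comps in (base[::-1], base + [lib.get("Q1")], [base[1], base[0], base[2]]):
        got = [(r.components, r.substitution.items) for r in gt.aci_unify(goal, comps)]
        assert got == ref


def test_empty_goal_unifies_with_nothing_used():
    (r,) = gt.aci_unify(gt.Program(), [])
    assert r.components == () and len(r.substitution) == 0


# --------------------------------------------------------------------------- #
# apply_inst / assemble


def test_apply_inst_identity_on_ground_component(repressilator):
    _, lib = repressilator
    q1 = lib.get("Q1")
    assert gt.apply_inst(q1) == q1.normalized
    assert gt.apply_inst(q1, gt.Substitution((("g9", gt.const("X")),))) == q1.normalized


def test_apply_inst_grounds_a_variable_component_and_checks_observability():
    comp = gt.Component("V1", gt.parse_program("x -> Out"))
    inst = gt.apply_inst(comp, gt.Substitution((("x", gt.const("In")),)))
    assert inst == gt.normalize(gt.parse_program("In -> Out"))
    blocked = gt.Component("V2", gt.parse_program("obs_1:: E\nE -> E"))
    with pytest.raises(gt.UnobservableError):
        gt.apply_inst(blocked)


def test_assemble_merges_partial_syntheses(repressilator):
    goal, lib = repressilator
    g = gt.normalize(goal)
    p1_goal = gt.Program((g.rules[0],))
    p2_goal = gt.Program((g.rules[1],))
    forbidden = gt.constants_of(g)
    (r1,) = gt.aci_unify(p1_goal, [lib.get("Q2")], check_observable=True)
    (r2,) = gt.aci_unify(p2_goal, [lib.get("Q1")], check_observable=True)
    merged = gt.assemble(r1, r2, lib)
    assert merged.components == ("Q1", "Q2")
    assert merged.substitution.as_dict() == {"g1": "CI", "g2": "LacI"}
    # commutative after canonicalization
    swapped = gt.assemble(r2, r1, lib)
    assert (swapped.components, swapped.substitution.items) == (
        merged.components, merged.substitution.items)
    # idempotent
    again = gt.assemble(merged, merged, lib)
    assert again.components == merged.components


def test_assemble_rejects_conflicting_substitutions(repressilator):
    goal, lib = repressilator
    g = gt.normalize(goal)
    (r1,) = gt.aci_unify(gt.Program((g.rules[0],)), [lib.get("Q2")])
    (r3,) = gt.aci_unify(gt.Program((g.rules[2],)), [lib.get("Q4")])
    assert r1.substitution.as_dict()["g1"] != r3.substitution.as_dict()["g1"]
    with pytest.raises(gt.SubstitutionConflictError):
        gt.assemble(r1, r3, lib)


# --------------------------------------------------------------------------- #
# brute-force oracle


def test_oracle_finds_the_unique_worked_example_solution(repressilator):
    goal, lib = repressilator
    oracle = gt.brute_force_oracle(goal, lib, 3)
    assert len(oracle) == 1
    ((names, sigma),) = oracle
    assert names == frozenset({"Q1", "Q2", "Q3"})
    assert dict(sigma) == {"g1": gt.const("CI"), "g2": gt.const("LacI")}


def test_oracle_on_empty_goal(repressilator):
    _, lib = repressilator
    assert gt.brute_force_oracle(gt.Program(), lib, 1) == {(frozenset(), ())}


def test_oracle_finds_symmetric_solutions():
    lib = gt.ComponentLibrary((
        gt.Component("S1", gt.parse_program("X -> !Y")),
        gt.Component("S2", gt.parse_program("Y -> !X")),
    ))
    goal = gt.parse_program("a -> !b")
    oracle = gt.brute_force_oracle(goal, lib, 1)
    assert oracle == {
        (frozenset({"S1"}), (("a", gt.const("X")), ("b", gt.const("Y")))),
        (frozenset({"S2"}), (("a", gt.const("Y")), ("b", gt.const("X")))),
    }


def test_oracle_resource_guard():
    comps = tuple(gt.Component(f"Z{i}", gt.parse_program("A -> B"))
                  for i in range(1, 10))
    with pytest.raises(gt.ResourceGuardExceeded):
        gt.brute_force_oracle(gt.parse_program("A -> B"),
                              gt.ComponentLibrary(comps), 1)


# --------------------------------------------------------------------------- #
# pipeline == oracle on random instances


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_pipeline_matches_oracle_on_solvable_instances(seed):
    pair = small_instance(seed)
    if pair is None:
        return
    lib, goal = pair
    oracle = gt.brute_force_oracle(goal, lib, len(gt.normalize(goal).rules))
    assert pipeline_solution_set(goal, lib) == oracle
    assert oracle  # solvable by construction


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_pipeline_matches_oracle_on_unconstrained_goals(seed):
    import random

    cfg = gt.BenchConfig(n_components=4, rules_per_component=(1, 2),
                         n_goal_rules=3, n_variables=2, n_constants=5, seed=seed)
    lib, _ = gt.generate(cfg)
    goal = gt.random_program(cfg, random.Random(seed + 1), n_rules=2, n_variables=1)
    oracle = gt.brute_force_oracle(goal, lib, len(gt.normalize(goal).rules))
    assert pipeline_solution_set(goal, lib) == oracle


# --------------------------------------------------------------------------- #
# soundness of every emitted solution


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_solutions_are_sound_wrt_behavioural_inclusion(seed):
    pair = small_instance(seed)
    if pair is None:
        return
    lib, goal = pair
    try:
        report = gt.compile(goal, lib, gt.SearchConfig(seed=seed))
    except gt.NoSolutionError:
        return
    g = gt.normalize(goal)
    bound = len(g.rules) + 2
    for r in report.solutions:
        ground_goal = r.substitution.apply(g)
        assert gt.observable(r.assembly)
        assert gt.behaviourally_includes(r.assembly, ground_goal, bound)
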